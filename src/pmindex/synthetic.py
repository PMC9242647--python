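"""Ground-truthed synthetic time-lapse movies of membrane-binding biosensors.

The generator produces multi-channel stacks in which each sensor's mass per
cell is conserved and repartitioned between plasma membrane (PM), an
intracellular puncta pool and the cytosol according to a piecewise-exponential
occupancy model of a hypoxia -> reoxygenation (or ATP inhibition -> washout)
time course. Every rendered movie carries exact per-frame ground truth so the
measurement pipeline can be validated end to end without real microscopy data.

Occupancy model, per sensor. Before stress onset the PM occupancy is 1; after
onset an optional transient overshoot (an alpha-function bump, continuous at
onset) may precede a delayed exponential decay toward ``floor``; after
reoxygenation plus a sensor-specific delay the occupancy relaxes
exponentially toward ``plateau``. All pieces join continuously by
construction. The puncta pool follows the same family with its own delays.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import disk as disk_coords
from skimage.measure import find_contours
from skimage.morphology import disk
from skimage.segmentation import find_boundaries
from shapely.geometry import Polygon

from .io import ImageStack
from .rois import RoiSpec

__all__ = [
    "SensorKinetics",
    "KineticModel",
    "TissueGeometry",
    "GroundTruth",
    "default_model",
    "generate_geometry",
    "simulate_occupancy",
    "render_stack",
    "half_time",
    "simulate_index_series",
    "roi_for_cell",
    "DEFAULT_SENSORS",
]

DEFAULT_SENSORS = ("PI4P", "PIP2", "Lgl", "ATP", "dye")


class GeometryError(ValueError):
    """Impossible cell packing for the requested field of view."""


# ============================================================== kinetic model

@dataclass
class SensorKinetics:
    """Piecewise-exponential PM occupancy parameters for one sensor.

    Times are seconds relative to the stress/relief events held by the parent
    :class:`KineticModel`; rates are 1/s; ``floor``/``plateau`` are occupancy
    fractions in [0, 1].
    """

    depletion_delay: float = 0.0
    depletion_rate: float = 0.0
    floor: float = 1.0
    recovery_delay: float = 0.0
    recovery_rate: float = 0.0
    plateau: float = 1.0
    overshoot_amp: float = 0.0
    overshoot_decay: float = 0.0           # 1/s; alpha-bump peaks at 1/decay after onset
    puncta_fraction: float = 0.0           # fraction of sensor mass in puncta at baseline
    puncta_depletion_delay: float = 0.0
    puncta_recovery_delay: float = 0.0
    pm_fraction: float = 0.6               # fraction of mass on the PM at occupancy 1

    def validate(self, name: str = "?") -> None:
        if not (0.0 <= self.floor <= self.plateau <= 1.0 + self.overshoot_amp):
            raise ValueError(
                f"sensor {name}: need 0 <= floor <= plateau <= 1 + overshoot_amp"
            )
        for attr in ("depletion_delay", "depletion_rate", "recovery_delay",
                     "recovery_rate", "overshoot_amp", "overshoot_decay",
                     "puncta_depletion_delay", "puncta_recovery_delay"):
            if getattr(self, attr) < 0:
                raise ValueError(f"sensor {name}: {attr} must be >= 0")
        if not (0.0 <= self.puncta_fraction < 1.0):
            raise ValueError(f"sensor {name}: puncta_fraction must be in [0, 1)")
        if not (0.0 < self.pm_fraction <= 1.0):
            raise ValueError(f"sensor {name}: pm_fraction must be in (0, 1]")
        if self.pm_fraction + self.puncta_fraction > 1.0:
            raise ValueError(f"sensor {name}: pm_fraction + puncta_fraction > 1")


@dataclass
class KineticModel:
    """Stress timeline plus per-sensor occupancy kinetics."""

    t_hypoxia: float
    t_reoxy: float
    sensors: dict[str, SensorKinetics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t_hypoxia < self.t_reoxy:
            raise ValueError("t_hypoxia must precede t_reoxy")
        for name, k in self.sensors.items():
            k.validate(name)

    def sensor(self, name: str) -> SensorKinetics:
        try:
            return self.sensors[name]
        except KeyError:
            raise KeyError(
                f"unknown sensor {name!r}; model defines {sorted(self.sensors)}"
            ) from None

    def to_dict(self) -> dict:
        return {
            "t_hypoxia": self.t_hypoxia,
            "t_reoxy": self.t_reoxy,
            "sensors": {n: asdict(k) for n, k in self.sensors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(
            t_hypoxia=d["t_hypoxia"],
            t_reoxy=d["t_reoxy"],
            sensors={n: SensorKinetics(**k) for n, k in d["sensors"].items()},
        )


def default_model(t_hypoxia: float = 600.0, t_reoxy: float = 3600.0) -> KineticModel:
    """Shipped defaults: 60 s frames, stress at frame 10, relief at frame 60.

    Depletion half-times order Lgl < PIP2 < PI4P and recovery half-times
    PI4P < PIP2 < Lgl. The PI4P channel carries a transient early overshoot
    (amplitude 0.15, a free choice - the magnitude is not constrained by any
    measurement) and an intracellular puncta pool that empties before and
    refills after the PM pool.
    """
    sensors = {
        "PI4P": SensorKinetics(
            depletion_delay=480.0, depletion_rate=0.0030, floor=0.12,
            recovery_delay=30.0, recovery_rate=0.010, plateau=0.95,
            overshoot_amp=0.15, overshoot_decay=1.0 / 200.0,
            puncta_fraction=0.20, puncta_depletion_delay=60.0,
            puncta_recovery_delay=480.0, pm_fraction=0.55,
        ),
        "PIP2": SensorKinetics(
            depletion_delay=180.0, depletion_rate=0.0035, floor=0.10,
            recovery_delay=240.0, recovery_rate=0.006, plateau=0.95,
            pm_fraction=0.60,
        ),
        "Lgl": SensorKinetics(
            depletion_delay=60.0, depletion_rate=0.0040, floor=0.08,
            recovery_delay=480.0, recovery_rate=0.005, plateau=0.92,
            pm_fraction=0.60,
        ),
        "ATP": SensorKinetics(
            depletion_delay=30.0, depletion_rate=0.0050, floor=0.25,
            recovery_delay=60.0, recovery_rate=0.009, plateau=1.0,
            pm_fraction=0.01,
        ),
        "dye": SensorKinetics(pm_fraction=0.92),
    }
    return KineticModel(t_hypoxia=t_hypoxia, t_reoxy=t_reoxy, sensors=sensors)


def _occupancy_curve(t, t_stress: float, t_relief: float, dep_delay: float,
                     dep_rate: float, floor: float, rec_delay: float,
                     rec_rate: float, plateau: float,
                     overshoot_amp: float = 0.0, overshoot_decay: float = 0.0):
    """Continuous piecewise occupancy; scalar or vectorized in ``t``."""
    t = np.asarray(t, dtype=float)

    def bump(tt):
        if overshoot_amp == 0.0 or overshoot_decay <= 0.0:
            return np.zeros_like(np.asarray(tt, dtype=float))
        x = np.maximum((np.asarray(tt, dtype=float) - t_stress) * overshoot_decay, 0.0)
        return overshoot_amp * x * np.exp(1.0 - x)

    t_on = t_stress + dep_delay
    t_rec = max(t_relief + rec_delay, t_on)
    f = 1.0 + bump(t)
    v_on = 1.0 + float(bump(t_on))
    decay = floor + (v_on - floor) * np.exp(-dep_rate * np.maximum(t - t_on, 0.0))
    f = np.where(t >= t_on, decay, f)
    v_rec = floor + (v_on - floor) * np.exp(-dep_rate * (t_rec - t_on))
    rise = plateau + (v_rec - plateau) * np.exp(-rec_rate * np.maximum(t - t_rec, 0.0))
    f = np.where(t >= t_rec, rise, f)
    return f if f.ndim else float(f)


def simulate_occupancy(model: KineticModel, sensor: str, t):
    """PM occupancy fraction f(t) in [0, 1 + overshoot_amp] for one sensor."""
    k = model.sensor(sensor)
    return _occupancy_curve(
        t, model.t_hypoxia, model.t_reoxy, k.depletion_delay, k.depletion_rate,
        k.floor, k.recovery_delay, k.recovery_rate, k.plateau,
        k.overshoot_amp, k.overshoot_decay,
    )


def simulate_puncta_occupancy(model: KineticModel, sensor: str, t):
    """Occupancy of the intracellular puncta pool (empties first, refills last)."""
    k = model.sensor(sensor)
    return _occupancy_curve(
        t, model.t_hypoxia, model.t_reoxy, k.puncta_depletion_delay,
        k.depletion_rate, k.floor, k.puncta_recovery_delay, k.recovery_rate,
        k.plateau,
    )


def half_time(model: KineticModel, sensor: str, phase: str,
              t_max: float | None = None, dt: float = 1.0) -> float:
    """Time at which occupancy crosses halfway between its bounding levels.

    ``phase='depletion'``: first crossing of (1 + floor)/2 after stress onset;
    ``phase='recovery'``: first crossing of (floor + plateau)/2 after relief.
    """
    k = model.sensor(sensor)
    if phase == "depletion":
        t0, t1 = model.t_hypoxia, model.t_reoxy
        target = (1.0 + k.floor) / 2.0
        grid = np.arange(t0, t1, dt)
        f = simulate_occupancy(model, sensor, grid)
        below = np.nonzero(f <= target)[0]
    elif phase == "recovery":
        t0 = model.t_reoxy
        t1 = t_max if t_max is not None else model.t_reoxy + 20.0 / max(k.recovery_rate, 1e-6)
        target = (k.floor + k.plateau) / 2.0
        grid = np.arange(t0, t1, dt)
        f = simulate_occupancy(model, sensor, grid)
        below = np.nonzero(f >= target)[0]
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if below.size == 0:
        return float("nan")
    return float(grid[below[0]])


# ================================================================== geometry

@dataclass
class TissueGeometry:
    """Label map plus the derived masks the renderer partitions mass into."""

    cell_label_image: np.ndarray               # int; 0 = background
    membrane_mask: np.ndarray                  # bool band along cell boundaries
    nuclei_mask: np.ndarray                    # bool
    puncta_centers: dict[int, np.ndarray]      # label -> (n, 2) row/col
    pixel_size_um: float = 0.2
    mode: str = "tissue"
    membrane_width_px: int = 3
    puncta_radius_px: int = 3

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.cell_label_image)
        return labs[labs > 0]

    def cell_mask(self, label: int) -> np.ndarray:
        return self.cell_label_image == label

    def puncta_mask(self, label: int | None = None) -> np.ndarray:
        """Disks of ``puncta_radius_px`` around puncta centers (one cell or all)."""
        out = np.zeros(self.cell_label_image.shape, dtype=bool)
        items = (
            self.puncta_centers.items() if label is None
            else [(label, self.puncta_centers.get(label, np.empty((0, 2))))]
        )
        for lab, centers in items:
            inside = self.cell_label_image == lab
            for r, c in np.atleast_2d(centers):
                rr, cc = disk_coords((r, c), self.puncta_radius_px,
                                     shape=self.cell_label_image.shape)
                keep = inside[rr, cc] & ~self.membrane_mask[rr, cc] & ~self.nuclei_mask[rr, cc]
                out[rr[keep], cc[keep]] = True
        return out


def generate_geometry(n_cells: int, image_shape: tuple[int, int],
                      mode: str = "tissue", seed: int = 0, *,
                      membrane_width_px: int = 3, margin: int = 8,
                      puncta_per_cell: int = 4, puncta_radius_px: int = 3,
                      pixel_size_um: float = 0.2) -> TissueGeometry:
    """Lay out cells and derive membrane/nucleus/puncta masks.

    ``tissue`` mode tiles an inset region with polygonal cells from a
    jittered-seed Voronoi partition (a margin of background is kept so the
    whole-image minimum is a true background reading); ``single_cell`` mode
    places non-touching round cells. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    usable = max(h - 2 * margin, 0) * max(w - 2 * margin, 0)
    if n_cells * 200 > usable:
        raise GeometryError(
            f"cannot pack {n_cells} cells of >= 200 px^2 into {image_shape} "
            f"(usable interior {usable} px^2)"
        )

    labels = np.zeros((h, w), dtype=np.int32)
    if mode == "tissue":
        side = int(np.ceil(np.sqrt(n_cells)))
        gy = np.linspace(margin, h - margin, side + 1)
        gx = np.linspace(margin, w - margin, side + 1)
        cy = (gy[:-1] + gy[1:]) / 2
        cx = (gx[:-1] + gx[1:]) / 2
        pts = np.array([(y, x) for y in cy for x in cx])[:n_cells]
        jitter = (gy[1] - gy[0]) * 0.22
        pts = pts + rng.uniform(-jitter, jitter, pts.shape)
        tree = cKDTree(pts)
        rr, cc = np.mgrid[margin:h - margin, margin:w - margin]
        _, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
        labels[margin:h - margin, margin:w - margin] = idx.reshape(rr.shape) + 1
    elif mode == "single_cell":
        radius = int(np.sqrt(usable / (n_cells * np.pi)) * 0.55)
        radius = int(np.clip(radius, 9, min(h, w) // 4))
        centers: list[tuple[float, float]] = []
        for _ in range(5000):
            if len(centers) == n_cells:
                break
            cand = rng.uniform(margin + radius, [h - margin - radius, w - margin - radius])
            if all(np.hypot(cand[0] - y, cand[1] - x) > 2 * radius + 4 for y, x in centers):
                centers.append(tuple(cand))
        if len(centers) < n_cells:
            raise GeometryError(
                f"could not place {n_cells} non-touching cells of radius {radius} "
                f"in {image_shape}"
            )
        for i, (y, x) in enumerate(centers):
            rr, cc = disk_coords((y, x), radius, shape=(h, w))
            labels[rr, cc] = i + 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    areas = np.bincount(labels.ravel(), minlength=n_cells + 1)[1:]
    if (areas < 200).any():
        raise GeometryError(
            f"smallest generated cell is {areas.min()} px^2 (< 200); "
            "enlarge the field or reduce n_cells"
        )

    boundaries = find_boundaries(labels, mode="thick") & (labels > 0)
    grow = max((membrane_width_px - 1) // 2, 0)
    membrane = (ndimage.binary_dilation(boundaries, structure=disk(grow))
                if grow else boundaries)
    membrane &= labels > 0

    nuclei = np.zeros((h, w), dtype=bool)
    puncta: dict[int, np.ndarray] = {}
    for lab in range(1, n_cells + 1):
        cell = labels == lab
        interior = cell & ~membrane
        if not interior.any():
            continue
        ys, xs = np.nonzero(interior)
        cyc, cxc = ys.mean(), xs.mean()
        r_nuc = max(2, int(0.22 * np.sqrt(cell.sum())))
        rr, cc = disk_coords((cyc, cxc), r_nuc, shape=(h, w))
        keep = interior[rr, cc]
        nuclei[rr[keep], cc[keep]] = True
        # puncta must clear the membrane and nucleus by their own radius,
        # or their rendered disks merge with the band
        free = ndimage.binary_erosion(
            interior & ~nuclei, structure=disk(puncta_radius_px + 2)
        )
        ys, xs = np.nonzero(free)
        if ys.size and puncta_per_cell > 0:
            pick = rng.choice(ys.size, size=min(puncta_per_cell, ys.size), replace=False)
            puncta[lab] = np.column_stack([ys[pick], xs[pick]]).astype(float)
        else:
            puncta[lab] = np.empty((0, 2))

    assert not (membrane & nuclei).any()
    return TissueGeometry(
        cell_label_image=labels, membrane_mask=membrane, nuclei_mask=nuclei,
        puncta_centers=puncta, pixel_size_um=pixel_size_um, mode=mode,
        membrane_width_px=membrane_width_px, puncta_radius_px=puncta_radius_px,
    )


def roi_for_cell(geometry: TissueGeometry, label: int, simplify_px: float = 1.0,
                 kind: str = "cell_region") -> RoiSpec:
    """Polygon ROI tracing one cell (membrane band included) from ground truth."""
    mask = geometry.cell_mask(label)
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError(f"label {label} not present in geometry")
    contour = max(contours, key=len)
    poly = Polygon(contour).buffer(0.6)
    if simplify_px > 0:
        poly = poly.simplify(simplify_px)
    verts = np.asarray(poly.exterior.coords)[:-1]
    h, w = mask.shape
    verts[:, 0] = np.clip(verts[:, 0], 0, h - 1)
    verts[:, 1] = np.clip(verts[:, 1], 0, w - 1)
    return RoiSpec(label=f"cell{label}", vertices=verts, kind=kind)


# ================================================================== rendering

@dataclass
class GroundTruth:
    """Exact noiseless/undrifted per-cell measurements for every frame.

    ``per_cell`` columns: frame, time_s, cell, channel, occupancy,
    puncta_occupancy, pm_mean, cyto_mean, background, pm_index.
    ``drift`` columns: frame, dy, dx (the applied whole-frame translation).
    """

    per_cell: pd.DataFrame
    drift: pd.DataFrame
    background: float
    noiseless: ImageStack | None = None

    def series(self, cell: int, channel: str, column: str = "pm_index") -> np.ndarray:
        sel = self.per_cell[(self.per_cell.cell == cell) & (self.per_cell.channel == channel)]
        return sel.sort_values("frame")[column].to_numpy()


def render_stack(geometry: TissueGeometry, model: KineticModel,
                 channels: list[str] | None = None, n_frames: int = 90,
                 frame_interval: float = 60.0,
                 amplitudes: dict[str, float] | None = None,
                 noise: dict | None = None, drift: dict | None = None,
                 seed: int = 0, background: float = 10.0,
                 keep_noiseless: bool = False) -> tuple[ImageStack, GroundTruth]:
    """Render the movie and its exact ground truth.

    Per frame and cell, each sensor's total mass ``amplitude x cell area`` is
    split PM : puncta : cytosol as ``pm_fraction x f(t)`` /
    ``puncta_fraction x p(t)`` / remainder, and spread uniformly over the
    corresponding pixel sets (nuclei hold no sensor). The ATP channel is
    intensimetric: cytosolic brightness proportional to its occupancy, mass
    not conserved. A random-walk whole-frame translation is applied, then
    Poisson shot noise (scaled by ``gain``) and Gaussian read noise.
    Ground truth is measured on the noiseless, undrifted render.
    """
    if channels is None:
        channels = [c for c in DEFAULT_SENSORS if c in model.sensors]
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    for ch in channels:
        model.sensor(ch)  # raises on unknown sensor
    amplitudes = dict(amplitudes or {})
    for ch in channels:
        amplitudes.setdefault(ch, 120.0)
        if amplitudes[ch] <= 0:
            raise ValueError(f"amplitude for {ch!r} must be > 0")
    noise = {"gain": 1.0, "read_sigma": 2.0, **(noise or {})}
    drift = {"step_sigma": 0.0, **(drift or {})}
    if not np.isfinite([noise["gain"], noise["read_sigma"]]).all():
        raise ValueError("noise parameters must be finite")
    if noise["gain"] < 0 or noise["read_sigma"] < 0:
        raise ValueError("noise parameters must be >= 0")

    rng = np.random.default_rng(seed)
    h, w = geometry.cell_label_image.shape
    labels = geometry.cell_label_image
    cell_ids = list(geometry.labels)
    times = np.arange(n_frames) * float(frame_interval)

    # per-cell compartment pixel sets (fixed over time)
    puncta_all = geometry.puncta_mask()
    comp: dict[int, dict[str, np.ndarray]] = {}
    for lab in cell_ids:
        cell = labels == lab
        pm = cell & geometry.membrane_mask
        pu = cell & puncta_all
        cyto = cell & ~geometry.membrane_mask & ~geometry.nuclei_mask & ~puncta_all
        comp[lab] = {"cell": cell, "pm": pm, "puncta": pu, "cyto": cyto,
                     "area": float(cell.sum())}

    occ = {ch: simulate_occupancy(model, ch, times) for ch in channels}
    pocc = {ch: simulate_puncta_occupancy(model, ch, times) for ch in channels}

    # label images per compartment (0 = not in that compartment) let each
    # frame be composed by a single per-cell table lookup
    n_lab = int(labels.max()) + 1
    pm_lab = np.where(geometry.membrane_mask, labels, 0)
    pu_lab = np.where(puncta_all, labels, 0)
    cy_lab = np.where(
        (labels > 0) & ~geometry.membrane_mask & ~geometry.nuclei_mask & ~puncta_all,
        labels, 0,
    )
    clean = np.full((n_frames, len(channels), h, w), background, dtype=np.float64)
    records = []
    for ci, ch in enumerate(channels):
        k = model.sensor(ch)
        pm_val = np.zeros((n_frames, n_lab))
        pu_val = np.zeros((n_frames, n_lab))
        cy_val = np.zeros((n_frames, n_lab))
        for lab in cell_ids:
            c = comp[lab]
            n_pm, n_pu, n_cy = c["pm"].sum(), c["puncta"].sum(), c["cyto"].sum()
            mass = amplitudes[ch] * c["area"]
            if ch == "ATP":
                cy_val[:, lab] = amplitudes[ch] * occ[ch]
            else:
                f_pm = k.pm_fraction * occ[ch]
                f_pu = (k.puncta_fraction * pocc[ch]) if n_pu else np.zeros(n_frames)
                f_cy = 1.0 - f_pm - f_pu
                if n_pm:
                    pm_val[:, lab] = mass * f_pm / n_pm
                if n_pu:
                    pu_val[:, lab] = mass * f_pu / n_pu
                if n_cy:
                    cy_val[:, lab] = mass * f_cy / n_cy
            for t in range(n_frames):
                if ch == "ATP":
                    pm_mean, cyto_mean, pmi = background, background + cy_val[t, lab], np.nan
                else:
                    pm_mean = background + pm_val[t, lab]
                    cyto_mean = background + cy_val[t, lab]
                    pmi = pm_val[t, lab] / cy_val[t, lab] if cy_val[t, lab] > 0 else np.nan
                records.append(
                    (t, times[t], lab, ch, float(occ[ch][t]), float(pocc[ch][t]),
                     pm_mean, cyto_mean, background, pmi)
                )
        clean[:, ci] += pm_val[:, pm_lab] + pu_val[:, pu_lab] + cy_val[:, cy_lab]

    # random-walk drift (frame 0 at origin)
    steps = rng.normal(0.0, drift["step_sigma"], size=(n_frames, 2))
    steps[0] = 0.0
    track = np.cumsum(steps, axis=0)
    if drift["step_sigma"] == 0:
        track[:] = 0.0

    rendered = np.empty_like(clean)
    for t in range(n_frames):
        if np.any(track[t]):
            for ci in range(len(channels)):
                rendered[t, ci] = ndimage.shift(
                    clean[t, ci], track[t], order=1, mode="constant", cval=background
                )
        else:
            rendered[t] = clean[t]

    if noise["gain"] > 0:
        rendered = rng.poisson(rendered / noise["gain"]) * noise["gain"]
    if noise["read_sigma"] > 0:
        rendered = rendered + rng.normal(0.0, noise["read_sigma"], rendered.shape)
    rendered = rendered.astype(np.float32)

    stack = ImageStack(
        data=rendered, channels=list(channels), pixel_size_um=geometry.pixel_size_um,
        frame_interval_s=float(frame_interval),
        metadata={"seed": seed, "background": background,
                  "t_hypoxia": model.t_hypoxia, "t_reoxy": model.t_reoxy},
    )
    gt = GroundTruth(
        per_cell=pd.DataFrame(
            records,
            columns=["frame", "time_s", "cell", "channel", "occupancy",
                     "puncta_occupancy", "pm_mean", "cyto_mean", "background",
                     "pm_index"],
        ),
        drift=pd.DataFrame(
            {"frame": np.arange(n_frames), "dy": track[:, 0], "dx": track[:, 1]}
        ),
        background=background,
        noiseless=ImageStack(
            data=clean.astype(np.float32), channels=list(channels),
            pixel_size_um=geometry.pixel_size_um, frame_interval_s=float(frame_interval),
        ) if keep_noiseless else None,
    )
    return stack, gt


# ===================================================== series-level simulator

def simulate_index_series(model: KineticModel, sensor: str, n_frames: int = 90,
                          frame_interval: float = 60.0, *,
                          area_fractions: tuple[float, float] = (0.15, 0.70),
                          noise_sigma: float = 0.0,
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """PM-index time series implied by the occupancy model, without rendering.

    Uses the same mass-partition arithmetic as :func:`render_stack` with
    nominal PM/cytosol area fractions, so the returned trajectory equals what
    a perfect measurement of a rendered movie would produce. Optional i.i.d.
    Gaussian observation noise. Returns ``(times_s, pm_index)``.
    """
    k = model.sensor(sensor)
    t = np.arange(n_frames) * float(frame_interval)
    f = simulate_occupancy(model, sensor, t)
    p = simulate_puncta_occupancy(model, sensor, t) if k.puncta_fraction else np.zeros_like(t)
    a_pm, a_cy = area_fractions
    f_pm = k.pm_fraction * f
    f_cy = 1.0 - f_pm - k.puncta_fraction * p
    y = (f_pm / a_pm) / (f_cy / a_cy)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    return t, y


def jittered_model(model: KineticModel, rng: np.random.Generator,
                   rate_cv: float = 0.10, delay_sd: float = 30.0) -> KineticModel:
    """Per-cell biological variability: lognormal rates, jittered delays."""
    out = {}
    for name, k in model.sensors.items():
        kk = SensorKinetics(**asdict(k))
        for attr in ("depletion_rate", "recovery_rate"):
            v = getattr(kk, attr)
            if v > 0:
                setattr(kk, attr, float(v * rng.lognormal(0.0, rate_cv)))
        for attr in ("depletion_delay", "recovery_delay"):
            v = getattr(kk, attr)
            setattr(kk, attr, float(max(v + rng.normal(0.0, delay_sd), 0.0)))
        out[name] = kk
    return KineticModel(t_hypoxia=model.t_hypoxia, t_reoxy=model.t_reoxy, sensors=out)


# ==================================================================== export

def write_simulation(out_dir: str | Path, stack: ImageStack, model: KineticModel,
                     gt: GroundTruth, seed: int) -> dict[str, Path]:
    """Write movie + sidecars: TIFF stack, model JSON, ground-truth CSVs."""
    from .io import write_stack, write_provenance

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": write_stack(stack, out_dir / "movie.tif"),
        "model": out_dir / "kinetic_model.json",
        "ground_truth": out_dir / "ground_truth.csv",
        "drift": out_dir / "drift.csv",
    }
    paths["model"].write_text(json.dumps({"seed": seed, **model.to_dict()}, indent=2))
    gt.per_cell.to_csv(paths["ground_truth"], index=False)
    gt.drift.to_csv(paths["drift"], index=False)
    write_provenance(out_dir, None, seed, extra={"tool": "simulate"})
    return paths
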