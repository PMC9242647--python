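"""Readers, writers and run configuration shared by all pipeline stages.

Canonical interchange is a plain multi-page TIFF (axes T,C,Y,X) with a JSON
sidecar / embedded shaped metadata; OME-XML axis strings are honored when
present but never required. ROIs travel as JSON, measurement tables as CSV.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .rois import RoiSpec

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "write_table",
    "read_table",
    "write_provenance",
]


class AxisInferenceError(ValueError):
    """Raised when the on-disk axis order cannot be determined."""


@dataclass
class ImageStack:
    """A time-lapse movie as a (T, C, Y, X) array with acquisition metadata."""

    data: np.ndarray
    channels: list[str]
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be 4-D (T,C,Y,X), got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[1]} channels"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None

    def channel(self, name: str) -> np.ndarray:
        """(T, Y, X) view of one channel."""
        return self.data[:, self.channel_index(name)]

    def frame(self, t: int, channel: str) -> np.ndarray:
        return self.data[t, self.channel_index(channel)]

    @property
    def saturation_level(self) -> float:
        """Intensity treated as saturated: dtype max for integer data,
        an explicit ``sat_level`` metadata entry, or +inf."""
        if "sat_level" in self.metadata:
            return float(self.metadata["sat_level"])
        if np.issubdtype(self.data.dtype, np.integer):
            return float(np.iinfo(self.data.dtype).max)
        return float("inf")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with embedded JSON metadata."""
    path = Path(path)
    meta = {
        "axes": "TCYX",
        "channels": list(stack.channels),
        "pixel_size_um": float(stack.pixel_size_um),
        "frame_interval_s": float(stack.frame_interval_s),
        **{k: v for k, v in stack.metadata.items() if _json_safe(v)},
    }
    tifffile.imwrite(path, stack.data, metadata=meta)
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_stack(path: str | Path, axis_hint: str | None = None) -> ImageStack:
    """Read a TIFF movie into a (T, C, Y, X) stack.

    Axis order is taken from embedded shaped/OME metadata, falling back to
    ``axis_hint`` (e.g. ``"TYX"``, ``"TCYX"``). Single-channel movies get a
    length-1 C axis. Ambiguous 3-D files without a hint raise
    :class:`AxisInferenceError` listing the candidate interpretations.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta: dict = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        axes = meta.get("axes")
        if axes is None and tif.series:
            file_axes = tif.series[0].axes
            if set(file_axes) <= set("TCYX"):
                axes = file_axes
    if axes is None:
        axes = axis_hint
    if data.ndim == 2:
        axes = axes or "YX"
    if axes is None:
        if data.ndim == 3:
            raise AxisInferenceError(
                f"{path}: 3-D TIFF without axis metadata; pass axis_hint='TYX' "
                "(time series, one channel) or 'CYX' (one frame, multi-channel)"
            )
        if data.ndim == 4:
            axes = "TCYX"
        else:
            raise AxisInferenceError(f"{path}: cannot interpret {data.ndim}-D TIFF")
    axes = axes.upper()
    if len(axes) != data.ndim:
        raise AxisInferenceError(
            f"{path}: axis string {axes!r} does not match array of {data.ndim} dimensions"
        )
    order = [axes.index(a) for a in "TCYX" if a in axes]
    data = np.transpose(data, order)
    for pos, a in enumerate("TCYX"):
        if a not in axes:
            data = np.expand_dims(data, pos)
    channels = meta.get("channels")
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"axes", "channels", "pixel_size_um", "frame_interval_s", "shape"}
    }
    return ImageStack(
        data=data,
        channels=list(channels),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
        metadata=extra,
    )


# --------------------------------------------------------------------------- ROIs

def read_rois(path: str | Path) -> list[RoiSpec]:
    """Read a list of polygon ROIs from JSON.

    Schema: ``[{"label": str, "kind": "junction"|"cell_region",
    "vertices": [[row, col], ...]}, ...]`` with 0-based pixel coordinates.
    Malformed polygons (fewer than 3 vertices, self-intersection) are rejected
    with an error naming the ROI label.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = raw.get("rois", [raw])
    rois = []
    for entry in raw:
        roi = RoiSpec(
            label=str(entry["label"]),
            vertices=np.asarray(entry["vertices"], dtype=float),
            kind=entry.get("kind", "junction"),
        )
        roi.validate()
        rois.append(roi)
    return rois


def write_rois(rois: list[RoiSpec], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"label": r.label, "kind": r.kind, "vertices": np.asarray(r.vertices).tolist()}
        for r in rois
    ]
    path.write_text(json.dumps(payload, indent=2))
    return path


# --------------------------------------------------------------------------- tables

TABLE_COLUMNS = [
    "movie_id", "roi", "channel", "frame", "time_s", "pm_mean", "cyto_mean",
    "background", "pm_index", "norm_pm_index", "n_pm_px", "n_cyto_px",
    "sat_frac", "valid",
]


def write_table(series_list, path: str | Path) -> Path:
    """Write PM-index series to CSV using the canonical column set."""
    frames = [s.to_frame() for s in series_list]
    table = pd.concat(frames, ignore_index=True)
    for col in TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[TABLE_COLUMNS]
    table.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Pipeline configuration; every knob the CLI exposes lives here."""

    pixel_size_um: float = 0.2
    frame_interval_s: float = 60.0
    channel_map: dict = field(default_factory=dict)
    mask_method: str = "atrous"            # atrous | mean
    mask_channel: str | None = "dye"
    guard_px: int = 1
    wavelet_levels: tuple = (1, 2)
    k_sigma: float = 3.0
    min_area_px: int = 10
    background_method: str = "min"         # min | percentile
    background_percentile: float = 0.1
    baseline_n: int = 3
    normalization: str = "index_minus_one"  # index_minus_one | plain
    # masks and background always come from the denoised working copy;
    # intensity means default to raw pixels because the Gaussian smoother
    # (unlike a structure-preserving wavelet denoiser) dilutes thin membrane
    # bands and would bias the PM mean low.
    measure_on: str = "raw"                 # raw | denoised
    denoise_strength: float = 1.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")
        if self.normalization not in {"index_minus_one", "plain"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.mask_method not in {"atrous", "mean"}:
            raise ValueError(f"unknown mask method {self.mask_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "wavelet_levels" in raw:
            raw["wavelet_levels"] = tuple(raw["wavelet_levels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavelet_levels"] = list(d["wavelet_levels"])
        return d


def write_provenance(out_dir: str | Path, config: RunConfig | dict | None,
                     seed: int | None, extra: dict | None = None) -> Path:
    """Drop a machine-readable record (config + seed + version) beside outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict() if isinstance(config, RunConfig) else config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        record.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
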