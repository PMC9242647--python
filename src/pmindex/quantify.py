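"""PM localization index and normalized series.

The central statistic is the background-corrected ratio of mean PM to mean
cytosolic intensity:

    pm_index = (pm_mean - background) / (cyto_mean - background)

A value of 1 means no PM enrichment. Two normalization conventions are
offered: ``index_minus_one`` (default) rescales (pm_index - 1) by its mean
over the leading baseline frames, so 1 is the starting enrichment and 0 is a
fully cytosolic sensor; ``plain`` rescales pm_index itself.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageStack
from .rois import RoiSpec
from .segmentation import MaskSet, detect_background

__all__ = [
    "PMIndexSeries",
    "pm_index",
    "pm_index_series",
    "normalize_series",
    "cyto_intensity_series",
]

#: denominator guard, as a fraction of typical dynamic range
EPSILON = 1e-6


class QuantifyError(ValueError):
    pass


def pm_index(pm_mean: float, cyto_mean: float, background: float) -> float:
    """Scalar PM localization index; raises when the denominator vanishes."""
    denom = cyto_mean - background
    if not np.isfinite(denom) or denom <= EPSILON:
        raise QuantifyError(
            f"cytosol mean {cyto_mean} does not exceed background {background}"
        )
    return (pm_mean - background) / denom


@dataclass
class PMIndexSeries:
    """Per-ROI, per-channel time series of PM indices with quality flags."""

    roi: str
    channel: str
    time_s: np.ndarray
    pm_mean: np.ndarray
    cyto_mean: np.ndarray
    background: np.ndarray
    pm_index: np.ndarray
    n_pm_px: np.ndarray
    n_cyto_px: np.ndarray
    sat_frac: np.ndarray
    valid: np.ndarray
    movie_id: str = ""
    norm_index: np.ndarray | None = None
    baseline_n: int | None = None
    baseline_value: float | None = None
    normalized: str | None = None            # None | index_minus_one | plain
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("pm_mean", "cyto_mean", "background", "pm_index",
                     "n_pm_px", "n_cyto_px", "sat_frac", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if n > 1 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "movie_id": self.movie_id,
            "roi": self.roi,
            "channel": self.channel,
            "frame": np.arange(self.n_frames),
            "time_s": self.time_s,
            "pm_mean": self.pm_mean,
            "cyto_mean": self.cyto_mean,
            "background": self.background,
            "pm_index": self.pm_index,
            "norm_pm_index": (self.norm_index if self.norm_index is not None
                              else np.full(self.n_frames, np.nan)),
            "n_pm_px": self.n_pm_px,
            "n_cyto_px": self.n_cyto_px,
            "sat_frac": self.sat_frac,
            "valid": self.valid,
        })


def _masked_mean(frame: np.ndarray, mask: np.ndarray, sat_level: float
                 ) -> tuple[float, int, int]:
    """Mean over mask excluding saturated pixels; returns (mean, n_used, n_sat)."""
    vals = frame[mask]
    sat = vals >= sat_level
    good = vals[~sat]
    if good.size == 0:
        return np.nan, 0, int(sat.sum())
    return float(good.mean()), int(good.size), int(sat.sum())


def pm_index_series(stack: ImageStack, masks: MaskSet, roi: RoiSpec, channel: str,
                    background_method: str = "min", background_p: float = 0.1,
                    background_stack: ImageStack | None = None,
                    movie_id: str = "") -> PMIndexSeries:
    """Per-frame PM index for one ROI and channel.

    Means are taken over the PM and cytosol masks with exclusions removed and
    saturated pixels dropped (their fraction is reported). Frames whose
    cytosol does not exceed background, or that are entirely saturated, are
    flagged invalid rather than poisoning the series with NaN arithmetic.
    ``background_stack`` lets background detection run on a denoised working
    copy while means are measured on ``stack``.
    """
    ci = stack.channel_index(channel)
    bg_stack = background_stack if background_stack is not None else stack
    sat_level = stack.saturation_level
    n = stack.n_frames
    out = {k: np.full(n, np.nan) for k in
           ("pm_mean", "cyto_mean", "background", "pm_index", "sat_frac")}
    n_pm = np.zeros(n, dtype=int)
    n_cy = np.zeros(n, dtype=int)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        key = (t, roi.label)
        if key not in masks.pm:
            raise QuantifyError(f"masks missing for frame {t}, ROI {roi.label!r}")
        frame = stack.data[t, ci]
        excl = masks.exclusions.get(key)
        pm_mask = masks.pm[key] if excl is None else masks.pm[key] & ~excl
        cy_mask = masks.cyto[key] if excl is None else masks.cyto[key] & ~excl
        pm_mean, n_pm[t], pm_sat = _masked_mean(frame, pm_mask, sat_level)
        cy_mean, n_cy[t], cy_sat = _masked_mean(frame, cy_mask, sat_level)
        total_px = int(pm_mask.sum() + cy_mask.sum())
        out["sat_frac"][t] = (pm_sat + cy_sat) / total_px if total_px else 1.0
        bg = detect_background(bg_stack.data[t, ci], background_method, background_p)
        out["background"][t] = bg
        out["pm_mean"][t] = pm_mean
        out["cyto_mean"][t] = cy_mean
        if not (np.isfinite(pm_mean) and np.isfinite(cy_mean)):
            continue
        denom = cy_mean - bg
        if denom <= EPSILON:
            continue
        out["pm_index"][t] = (pm_mean - bg) / denom
        valid[t] = True
    if not valid.any():
        raise QuantifyError(
            f"ROI {roi.label!r}, channel {channel!r}: no valid frames"
        )
    return PMIndexSeries(
        roi=roi.label, channel=channel, time_s=stack.times,
        pm_mean=out["pm_mean"], cyto_mean=out["cyto_mean"],
        background=out["background"], pm_index=out["pm_index"],
        n_pm_px=n_pm, n_cyto_px=n_cy, sat_frac=out["sat_frac"], valid=valid,
        movie_id=movie_id,
    )


def normalize_series(series: PMIndexSeries, baseline_n: int = 3,
                     convention: str = "index_minus_one") -> PMIndexSeries:
    """Scale a series against its leading-baseline value.

    ``index_minus_one``: N(t) = (PMI(t) - 1) / mean_baseline(PMI - 1);
    ``plain``: N(t) = PMI(t) / mean_baseline(PMI). The baseline is the first
    ``baseline_n`` valid frames. Normalizing an already-normalized series is
    a no-op (returned unchanged), making the operation idempotent. A baseline
    index indistinguishable from 1 under ``index_minus_one`` is an error
    naming the ROI: the sensor shows no PM enrichment to normalize against.
    """
    if convention not in {"index_minus_one", "plain"}:
        raise ValueError(f"unknown convention {convention!r}")
    if series.normalized is not None:
        return copy.deepcopy(series)
    if baseline_n < 1:
        raise ValueError("baseline_n must be >= 1")
    valid_idx = np.nonzero(series.valid)[0]
    base_idx = valid_idx[:baseline_n]
    if base_idx.size < 1:
        raise QuantifyError(f"ROI {series.roi!r}: no valid baseline frames")
    base_vals = series.pm_index[base_idx]
    out = copy.deepcopy(series)
    if convention == "index_minus_one":
        base = float(np.mean(base_vals - 1.0))
        if abs(base) <= EPSILON:
            raise QuantifyError(
                f"ROI {series.roi!r}: baseline PM index is ~1 (no PM enrichment); "
                "cannot normalize with convention 'index_minus_one'"
            )
        out.norm_index = (series.pm_index - 1.0) / base
    else:
        base = float(np.mean(base_vals))
        if abs(base) <= EPSILON:
            raise QuantifyError(f"ROI {series.roi!r}: baseline PM index is ~0")
        out.norm_index = series.pm_index / base
    out.baseline_n = int(baseline_n)
    out.baseline_value = base
    out.normalized = convention
    return out


def cyto_intensity_series(stack: ImageStack, masks: MaskSet, roi: RoiSpec,
                          channel: str, baseline_n: int = 3,
                          background_method: str = "min", background_p: float = 0.1,
                          movie_id: str = "") -> PMIndexSeries:
    """Normalized cytosolic intensity for intensimetric (single-compartment)
    sensors: background-subtracted mean over the cytosol mask, divided by its
    mean over the leading baseline frames. Stored in ``norm_index``;
    ``pm_index`` is NaN throughout.
    """
    ci = stack.channel_index(channel)
    sat_level = stack.saturation_level
    n = stack.n_frames
    cy_mean = np.full(n, np.nan)
    bgs = np.full(n, np.nan)
    sat_frac = np.full(n, np.nan)
    n_cy = np.zeros(n, dtype=int)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        key = (t, roi.label)
        if key not in masks.cyto:
            raise QuantifyError(f"masks missing for frame {t}, ROI {roi.label!r}")
        excl = masks.exclusions.get(key)
        mask = masks.cyto[key] if excl is None else masks.cyto[key] & ~excl
        m, n_cy[t], n_sat = _masked_mean(stack.data[t, ci], mask, sat_level)
        total = int(mask.sum())
        sat_frac[t] = n_sat / total if total else 1.0
        bgs[t] = detect_background(stack.data[t, ci], background_method, background_p)
        cy_mean[t] = m
        valid[t] = np.isfinite(m) and (m - bgs[t]) > EPSILON
    valid_idx = np.nonzero(valid)[0]
    if valid_idx.size == 0:
        raise QuantifyError(f"ROI {roi.label!r}, channel {channel!r}: no valid frames")
    base_idx = valid_idx[:baseline_n]
    base = float(np.mean(cy_mean[base_idx] - bgs[base_idx]))
    if base <= EPSILON:
        raise QuantifyError(f"ROI {roi.label!r}: baseline cytosolic intensity is ~0")
    norm = (cy_mean - bgs) / base
    return PMIndexSeries(
        roi=roi.label, channel=channel, time_s=stack.times,
        pm_mean=np.full(n, np.nan), cyto_mean=cy_mean, background=bgs,
        pm_index=np.full(n, np.nan), n_pm_px=np.zeros(n, dtype=int),
        n_cyto_px=n_cy, sat_frac=sat_frac, valid=valid, movie_id=movie_id,
        norm_index=norm, baseline_n=int(baseline_n), baseline_value=base,
        normalized="cyto_intensity",
    )
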