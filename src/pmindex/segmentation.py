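"""PM and cytosol mask generation plus background detection.

Two mask routes are provided, mirroring the two imaging contexts:

* ``mean`` — within a user ROI, PM pixels are those at or above the ROI mean
  intensity and cytosol pixels those strictly below it (the tie rule makes
  the two masks an exhaustive partition before exclusions).
* ``atrous`` — an undecimated a trous B3-spline wavelet decomposition; the
  sum of mid-scale detail planes is thresholded at ``k_sigma`` times a robust
  noise scale estimated from the finest detail plane. Detail planes are
  invariant to additive offsets, so this route is background-independent.

A 1-px guard ring (configurable) separates the cytosol mask from the PM mask
to suppress PSF bleed-through across the membrane.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .io import ImageStack
from .rois import RoiSpec

__all__ = [
    "AtrousDecomposition",
    "MaskSet",
    "atrous_decompose",
    "mean_threshold_pm_mask",
    "cytosol_mask",
    "wavelet_pm_mask",
    "detect_background",
    "detect_exclusions",
    "build_masks",
]

B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
#: MAD of a standard normal deviate
_MAD_TO_SIGMA = 0.6744897501960817


class SegmentationError(ValueError):
    pass


class EmptyMaskError(SegmentationError):
    pass


# ============================================================ a trous wavelet

@dataclass
class AtrousDecomposition:
    """Additive undecimated wavelet decomposition: input = sum(details) + residual."""

    details: list[np.ndarray]
    residual: np.ndarray
    levels: int

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.details, axis=0) + self.residual

    def detail_sum(self, levels: set[int] | tuple[int, ...]) -> np.ndarray:
        """Sum of 1-based detail planes ``levels``."""
        bad = [j for j in levels if not 1 <= j <= self.levels]
        if bad:
            raise ValueError(f"detail levels {bad} outside 1..{self.levels}")
        return np.sum([self.details[j - 1] for j in levels], axis=0)

    def noise_sigma(self) -> float:
        """Robust noise scale: MAD of the finest detail plane, scaled to sigma.

        Floored at a tenth of the plane's standard deviation so that
        noise-free (or aggressively denoised) images, whose MAD collapses to
        zero, still produce a usable detection threshold.
        """
        d1 = self.details[0]
        mad = float(np.median(np.abs(d1 - np.median(d1))) / _MAD_TO_SIGMA)
        return max(mad, 0.1 * float(d1.std()))


def _holey_kernel(level: int) -> np.ndarray:
    """B3-spline kernel with 2**(level-1) - 1 zeros between taps."""
    if level == 1:
        return B3_KERNEL
    step = 2 ** (level - 1)
    k = np.zeros((len(B3_KERNEL) - 1) * step + 1)
    k[::step] = B3_KERNEL
    return k


def atrous_decompose(image: np.ndarray, levels: int = 3) -> AtrousDecomposition:
    """A trous B3-spline decomposition with mirrored borders.

    The smoothing kernel [1,4,6,4,1]/16 is applied separably with
    2**(j-1) - 1 holes at level j; detail plane j is the difference of
    successive smooths. The decomposition telescopes: summing all detail
    planes and the residual reconstructs the input to float precision.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if min(image.shape) <= 2**levels * 4:
        raise SegmentationError(
            f"image of shape {image.shape} too small for {levels} levels "
            f"(min dimension must exceed {2**levels * 4})"
        )
    smooth = image
    details = []
    for j in range(1, levels + 1):
        k = _holey_kernel(j)
        nxt = ndimage.correlate1d(smooth, k, axis=0, mode="mirror")
        nxt = ndimage.correlate1d(nxt, k, axis=1, mode="mirror")
        details.append(smooth - nxt)
        smooth = nxt
    return AtrousDecomposition(details=details, residual=smooth, levels=levels)


# ============================================================== mask routes

def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop connected components smaller than ``min_area`` pixels."""
    lab, n = ndimage.label(mask)
    if not n:
        return mask
    areas = np.bincount(lab.ravel())
    keep = np.nonzero(areas >= min_area)[0]
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def mean_threshold_pm_mask(frame: np.ndarray, roi: RoiSpec
                           ) -> tuple[np.ndarray, float]:
    """PM mask: ROI pixels at or above the ROI mean intensity.

    Returns ``(mask, threshold)``; the threshold is the ROI mean. A constant
    ROI degenerates to the full ROI and triggers a warning.
    """
    frame = np.asarray(frame, dtype=np.float64)
    roi_mask = roi.mask(frame.shape)
    if not roi_mask.any():
        raise SegmentationError(f"ROI {roi.label!r} rasterizes to an empty mask")
    vals = frame[roi_mask]
    thr = float(vals.mean())
    if not np.isfinite(thr):
        raise SegmentationError(f"ROI {roi.label!r}: mean intensity is not finite")
    if np.ptp(vals) == 0:
        warnings.warn(
            f"ROI {roi.label!r} is constant; PM mask degenerates to the whole ROI",
            stacklevel=2,
        )
    return roi_mask & (frame >= thr), thr


def cytosol_mask(frame: np.ndarray, roi: RoiSpec, pm_mask: np.ndarray,
                 exclusions: np.ndarray | None = None, guard_px: int = 1,
                 threshold: float | None = None) -> np.ndarray:
    """Cytosol mask: ROI pixels strictly below the ROI-mean threshold,
    minus exclusions and a ``guard_px`` dilation ring around the PM mask."""
    frame = np.asarray(frame, dtype=np.float64)
    roi_mask = roi.mask(frame.shape)
    if not (pm_mask <= roi_mask).all() and (pm_mask & ~roi_mask).any():
        raise SegmentationError(f"ROI {roi.label!r}: pm_mask extends outside the ROI")
    if threshold is None:
        threshold = float(frame[roi_mask].mean())
    mask = roi_mask & (frame < threshold)
    guard = (ndimage.binary_dilation(pm_mask, structure=disk(guard_px))
             if guard_px > 0 else pm_mask)
    mask &= ~guard
    if exclusions is not None:
        mask &= ~exclusions
    if not mask.any():
        raise EmptyMaskError(
            f"ROI {roi.label!r}: cytosol mask is empty after exclusions; "
            "enlarge the ROI to include more cytoplasm"
        )
    return mask


def wavelet_pm_mask(frame: np.ndarray, roi: RoiSpec,
                    levels_used: tuple[int, ...] = (1, 2), k_sigma: float = 3.0,
                    min_area: int = 10,
                    decomposition: AtrousDecomposition | None = None
                    ) -> tuple[np.ndarray, float]:
    """PM mask from mid-scale wavelet detail planes.

    The detail sum over ``levels_used`` is thresholded at ``k_sigma`` times
    the robust noise sigma of the finest plane; components below ``min_area``
    px are dropped; the result is clipped to the ROI. Returns
    ``(mask, threshold)``. Offset-invariant by construction.
    """
    if decomposition is None:
        decomposition = atrous_decompose(np.asarray(frame, float), max(levels_used))
    d = decomposition.detail_sum(levels_used)
    if not np.any(d):
        raise SegmentationError("wavelet detail sum is identically zero")
    thr = k_sigma * decomposition.noise_sigma()
    mask = d > thr
    if min_area > 1:
        mask = _remove_small(mask, min_area)
    return mask & roi.mask(d.shape), thr


def detect_background(frame: np.ndarray, method: str = "min", p: float = 0.1) -> float:
    """Whole-frame background: global minimum (default) or the p-th percentile."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise SegmentationError("empty frame")
    if method == "min":
        return float(frame.min())
    if method == "percentile":
        return float(np.percentile(frame, p))
    raise ValueError(f"unknown background method {method!r}")


def detect_exclusions(frame: np.ndarray, roi: RoiSpec, k_sigma: float = 4.0,
                      puncta_max_area: int = 200, nucleus_min_area: int = 60,
                      puncta_pad_px: int = 2,
                      decomposition: AtrousDecomposition | None = None) -> np.ndarray:
    """Pixels to exclude from measurement: bright puncta and dim nuclei.

    Puncta: connected components of the level-1+2 wavelet detail sum above
    ``k_sigma`` x noise sigma whose area is at most ``puncta_max_area`` px
    (offset-invariant), padded by ``puncta_pad_px`` to swallow their halos.
    Nuclei: components below half the ROI median larger than
    ``nucleus_min_area`` px. May be empty.
    """
    frame = np.asarray(frame, dtype=np.float64)
    roi_mask = roi.mask(frame.shape)
    if not roi_mask.any():
        raise SegmentationError(f"ROI {roi.label!r} rasterizes to an empty mask")
    if decomposition is None:
        decomposition = atrous_decompose(frame, 2)
    d = decomposition.detail_sum((1, 2))
    bright = d > k_sigma * decomposition.noise_sigma()
    lab, n = ndimage.label(bright)
    out = np.zeros(frame.shape, dtype=bool)
    if n:
        areas = np.bincount(lab.ravel())
        small = np.isin(lab, np.nonzero((areas <= puncta_max_area))[0][1:])
        puncta = small & bright
        if puncta_pad_px > 0 and puncta.any():
            puncta = ndimage.binary_dilation(puncta, structure=disk(puncta_pad_px))
        out |= puncta
    dim = roi_mask & (frame < 0.5 * np.median(frame[roi_mask]))
    dim = _remove_small(dim, nucleus_min_area)
    out |= dim
    return out & roi_mask


# ================================================================= mask sets

@dataclass
class MaskSet:
    """Per-frame, per-ROI PM/cytosol/exclusion masks with their thresholds.

    Keys are ``(frame_index, roi_label)``; masks are full-frame booleans.
    """

    pm: dict = field(default_factory=dict)
    cyto: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    provenance: str = "atrous"
    fallback_frames: list = field(default_factory=list)

    def check_disjoint(self) -> None:
        for key in self.pm:
            if (self.pm[key] & self.cyto[key]).any():
                raise SegmentationError(f"pm and cyto masks overlap at {key}")


def build_masks(stack: ImageStack, rois: list[RoiSpec], method: str = "atrous",
                mask_channel: str | None = None, guard_px: int = 1,
                levels_used: tuple[int, ...] = (1, 2), k_sigma: float = 3.0,
                min_area: int = 10, exclusion_channels: list[str] | None = None,
                exclusion_k_sigma: float = 4.0,
                refine_intensity: bool = True) -> MaskSet:
    """Compute masks for every frame and ROI.

    When a membrane-dye channel is available it should drive the masks for
    all frames — the sensor channels leave the PM under stress and cannot
    define it. Without one, masks follow each frame of ``mask_channel``
    (or the first channel), falling back to the last non-empty PM mask when
    the membrane signal collapses (those frames are recorded in
    ``fallback_frames``).

    Exclusion masks (puncta + nuclei) are unioned over ``exclusion_channels``
    (default: every non-dye channel), since puncta live in sensor channels.
    """
    if mask_channel is None:
        mask_channel = "dye" if "dye" in stack.channels else stack.channels[0]
    if exclusion_channels is None:
        # membrane dyes carry no puncta/nuclei contrast and intensimetric
        # cytosolic sensors are dark on the PM (their "dim region" detector
        # would swallow the membrane band), so neither drives exclusions
        exclusion_channels = [c for c in stack.channels
                              if c not in {"dye", "ATP", "MaLionR"}]
    ms = MaskSet(provenance=method)
    last_pm: dict[str, np.ndarray] = {}
    for t in range(stack.n_frames):
        frame = stack.frame(t, mask_channel)
        decomp = None
        if method == "atrous":
            decomp = atrous_decompose(frame, max(levels_used))
        excl_decomps = {
            ch: atrous_decompose(stack.frame(t, ch), 2) for ch in exclusion_channels
        }
        for roi in rois:
            key = (t, roi.label)
            if method == "atrous":
                pm, thr = wavelet_pm_mask(
                    frame, roi, levels_used=levels_used, k_sigma=k_sigma,
                    min_area=min_area, decomposition=decomp,
                )
                if refine_intensity:
                    # clip the wavelet footprint to pixels at or above the
                    # ROI mean of the mask channel: detail planes respond a
                    # little beyond the bright band and those halo pixels
                    # would dilute the PM mean
                    roi_px = roi.mask(stack.frame_shape)
                    refined = pm & (frame >= frame[roi_px].mean())
                    if refined.any():
                        pm = refined
            elif method == "mean":
                pm, thr = mean_threshold_pm_mask(frame, roi)
            else:
                raise ValueError(f"unknown mask method {method!r}")
            if not pm.any():
                if roi.label in last_pm:
                    pm = last_pm[roi.label]
                    ms.fallback_frames.append(key)
                else:
                    raise EmptyMaskError(
                        f"frame {t}, ROI {roi.label!r}: empty PM mask and no "
                        "earlier mask to fall back to"
                    )
            else:
                last_pm[roi.label] = pm
            pm = pm & roi.mask(stack.frame_shape)
            # exclusions guard the cytosol measurement (puncta, nuclei); a
            # depleting sensor's fragmenting membrane signal looks punctate,
            # so the PM band is carved out of them, never the reverse
            excl = np.zeros(stack.frame_shape, dtype=bool)
            for ch in exclusion_channels:
                excl |= detect_exclusions(
                    stack.frame(t, ch), roi, k_sigma=exclusion_k_sigma,
                    decomposition=excl_decomps[ch],
                )
            excl &= ~pm
            try:
                cyto = cytosol_mask(frame, roi, pm, exclusions=excl,
                                    guard_px=guard_px)
            except EmptyMaskError:
                # degenerate frame (e.g. saturated everywhere); reuse the
                # previous frame's masks and flag it rather than aborting
                prev = (t - 1, roi.label)
                if prev not in ms.cyto:
                    raise
                pm = ms.pm[prev]
                cyto = ms.cyto[prev]
                excl = ms.exclusions[prev]
                ms.fallback_frames.append(key)
            ms.pm[key] = pm
            ms.cyto[key] = cyto
            ms.exclusions[key] = excl
            ms.thresholds[key] = thr
            if not ms.pm[key].any():
                raise EmptyMaskError(
                    f"frame {t}, ROI {roi.label!r}: PM mask empty after exclusions"
                )
    return ms
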