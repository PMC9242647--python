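"""Polygonal regions of interest in pixel coordinates.

Coordinates are (row, col), 0-based, pixel-centered, row 0 at the top.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

__all__ = ["RoiSpec", "RoiError"]


class RoiError(ValueError):
    """Malformed or out-of-bounds ROI."""


@dataclass
class RoiSpec:
    """A labeled simple polygon, the unit of quantification.

    ``kind`` distinguishes junction-spanning regions drawn across a cell-cell
    boundary from regions covering part of a single cell (PM plus cytoplasm).
    """

    label: str
    vertices: np.ndarray                       # (n, 2) float, (row, col)
    kind: str = "junction"                     # junction | cell_region
    target_area_um2: tuple[float, float] = (20.0, 40.0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)

    # ------------------------------------------------------------------ checks
    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        v = self.vertices
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise RoiError(f"ROI {self.label!r}: need >= 3 (row, col) vertices")
        if not np.isfinite(v).all():
            raise RoiError(f"ROI {self.label!r}: non-finite vertex")
        poly = Polygon(v)
        if not poly.is_simple:
            raise RoiError(f"ROI {self.label!r}: polygon is self-intersecting")
        if poly.area <= 0:
            raise RoiError(f"ROI {self.label!r}: zero-area polygon")
        if self.kind not in {"junction", "cell_region"}:
            raise RoiError(f"ROI {self.label!r}: unknown kind {self.kind!r}")
        if image_shape is not None:
            h, w = image_shape
            if (v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5
                    or v[:, 0].max() > h - 0.5 or v[:, 1].max() > w - 0.5):
                raise RoiError(f"ROI {self.label!r}: vertices outside image {image_shape}")

    # ---------------------------------------------------------------- geometry
    @property
    def area_px(self) -> float:
        return Polygon(self.vertices).area

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask of the given frame shape (cached)."""
        cached = getattr(self, "_mask_cache", None)
        if cached is not None and cached[0] == tuple(image_shape):
            return cached[1]
        m = polygon2mask(image_shape, self.vertices)
        object.__setattr__(self, "_mask_cache", (tuple(image_shape), m))
        return m

    def warn_if_outside_area_guidance(self, pixel_size_um: float) -> None:
        """Junction ROIs are conventionally ~20-40 um^2; warn, never enforce."""
        if self.kind != "junction" or not self.target_area_um2:
            return
        area_um2 = self.area_px * pixel_size_um**2
        lo, hi = self.target_area_um2
        if not (lo <= area_um2 <= hi):
            warnings.warn(
                f"ROI {self.label!r}: area {area_um2:.1f} um^2 outside "
                f"guidance [{lo}, {hi}] um^2", stacklevel=2,
            )

    def bounding_box(self, image_shape: tuple[int, int], pad: int = 0):
        """(row slice, col slice) enclosing the polygon, clipped to the image."""
        h, w = image_shape
        r0 = max(int(np.floor(self.vertices[:, 0].min())) - pad, 0)
        r1 = min(int(np.ceil(self.vertices[:, 0].max())) + pad + 1, h)
        c0 = max(int(np.floor(self.vertices[:, 1].min())) - pad, 0)
        c1 = min(int(np.ceil(self.vertices[:, 1].max())) + pad + 1, w)
        return slice(r0, r1), slice(c0, c1)
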