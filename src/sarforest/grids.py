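"""Shared grid containers and a minimal affine georeferencing model.

All rasters in this package are row-major 2-D numpy arrays with the
pixel-is-area convention: the grid origin is the *top-left corner* of the
top-left pixel, x increases with column index, y decreases with row index.
Square pixels only — one ``pixel_size_m`` covers both axes, which matches
the 50-m mosaic products this toolkit targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridTransform", "DualPolScene", "BackscatterStack"]


@dataclass(frozen=True)
class GridTransform:
    """Top-left-origin affine georeferencing for a square-pixel grid.

    Parameters
    ----------
    x0, y0 : float
        Map coordinates of the top-left corner of pixel (0, 0).
    pixel_size_m : float
        Side length of a pixel in metres (default 50, the mosaic pixel).
    """

    x0: float = 0.0
    y0: float = 0.0
    pixel_size_m: float = 50.0

    def pixel_center(self, row, col):
        """Map coordinates of pixel centers for (array-like) row/col."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x0 + (col + 0.5) * self.pixel_size_m
        y = self.y0 - (row + 0.5) * self.pixel_size_m
        return x, y

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "pixel_size_m": self.pixel_size_m}

    @classmethod
    def from_dict(cls, d: dict) -> "GridTransform":
        return cls(float(d["x0"]), float(d["y0"]), float(d["pixel_size_m"]))


def _as_bool_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {shape}")
    return mask


@dataclass
class DualPolScene:
    """Paired HH/HV digital-number (amplitude) grids with georeferencing.

    ``valid_mask`` is False wherever either polarization is 0 or missing:
    DN 0 is the mosaic fill value and never a measurement.
    """

    hh_dn: np.ndarray
    hv_dn: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.hh_dn = np.asarray(self.hh_dn)
        self.hv_dn = np.asarray(self.hv_dn)
        if self.hh_dn.shape != self.hv_dn.shape:
            raise ValueError(
                f"HH shape {self.hh_dn.shape} != HV shape {self.hv_dn.shape}"
            )
        if np.any(self.hh_dn < 0) or np.any(self.hv_dn < 0):
            raise ValueError("digital numbers are amplitudes and must be >= 0")
        mask = _as_bool_mask(self.valid_mask, self.hh_dn.shape)
        mask &= (self.hh_dn > 0) & (self.hv_dn > 0)
        self.valid_mask = mask

    @property
    def shape(self):
        return self.hh_dn.shape

    @property
    def pixel_size_m(self) -> float:
        return self.transform.pixel_size_m


@dataclass
class BackscatterStack:
    """Calibrated σ⁰ grids (dB) plus the derived difference and ratio bands.

    Invariants: on valid pixels ``diff_db == hh_db - hv_db`` exactly; the
    ratio band is HH_dB / HV_dB and is undefined (flagged in
    ``ratio_valid``) where HV is exactly 0 dB.
    """

    hh_db: np.ndarray
    hv_db: np.ndarray
    diff_db: np.ndarray
    ratio: np.ndarray
    valid_mask: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    ratio_valid: np.ndarray | None = None

    def __post_init__(self):
        shapes = {a.shape for a in (self.hh_db, self.hv_db, self.diff_db, self.ratio)}
        if len(shapes) != 1:
            raise ValueError("all stack bands must share one shape")
        self.valid_mask = _as_bool_mask(self.valid_mask, self.hh_db.shape)
        if self.ratio_valid is None:
            self.ratio_valid = self.valid_mask & (self.hv_db != 0)

    @property
    def shape(self):
        return self.hh_db.shape
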