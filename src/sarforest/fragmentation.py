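"""Riitters-style forest fragmentation from a binary forest mask.

Two indicators are computed in a square moving window around each pixel:

* **Pf** — forest area density, the proportion of forest pixels among the
  valid pixels in the window (N_f / N_w);
* **Pff** — forest connectivity, the conditional probability that a
  cardinally adjacent pixel pair that touches forest is entirely forest:
  (# pairs with both pixels forest) / (# pairs with at least one forest
  pixel), over all pairs fully inside the window.

Each forest pixel is then assigned one of six fragmentation categories:

====  =============  ==========================================
code  category       criterion
====  =============  ==========================================
1     patch          Pf < 0.4
2     transitional   0.4 ≤ Pf ≤ 0.6
3     perforated     Pf > 0.6 and Pf > Pff
4     undetermined   Pf > 0.6 and Pf = Pff (or Pff undefined)
5     edge           Pf > 0.6 and Pf < Pff
6     interior       Pf = 1
====  =============  ==========================================

Interior is tested first (Pf = 1 forces Pff = 1, which would otherwise
land in "undetermined"), and the boundary values Pf = 0.4 and 0.6 are
folded into "transitional" so the criteria partition [0, 1]. Windows are
truncated (not padded) at raster borders and around nodata: denominators
count only valid in-window pixels and pairs. All window sums are exact
integer counts, so the Pf = Pff comparison is decided exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridTransform

__all__ = [
    "CATEGORY_CODES",
    "CATEGORY_NAMES",
    "ForestMask",
    "FragmentationGrid",
    "forest_density",
    "forest_connectivity",
    "classify_fragmentation",
    "fragment_map",
    "fragmentation_summary",
]

CATEGORY_CODES = {
    "background": 0,
    "patch": 1,
    "transitional": 2,
    "perforated": 3,
    "undetermined": 4,
    "edge": 5,
    "interior": 6,
}
CATEGORY_NAMES = {v: k for k, v in CATEGORY_CODES.items()}


@dataclass
class ForestMask:
    """Binary forest map (forest = 1, non-forest = 0) with a validity mask."""

    mask: np.ndarray
    valid_mask: np.ndarray | None = None
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.valid_mask is None:
            self.valid_mask = self.mask >= 0
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.mask.shape:
            raise ValueError("valid_mask shape mismatch")
        vals = np.unique(self.mask[self.valid_mask])
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("forest mask must be 0/1 on valid pixels")
        self.mask = np.where(self.valid_mask, self.mask, 0).astype(np.int8)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def pixel_size_m(self) -> float:
        return self.transform.pixel_size_m

    def forest_pixel_count(self) -> int:
        return int((self.mask == 1).sum())


@dataclass
class FragmentationGrid:
    """Per-pixel Pf, Pff and fragmentation category for one window size.

    ``pff`` is NaN where no in-window pair touches forest. ``category`` is
    nonzero exactly on valid forest pixels.
    """

    pf: np.ndarray
    pff: np.ndarray
    category: np.ndarray
    window: int
    transform: GridTransform = field(default_factory=GridTransform)


def _check_window(window: int) -> int:
    window = int(window)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    return window


def _windowed_sum(arr: np.ndarray, up: int, down: int, left: int, right: int,
                  out_shape) -> np.ndarray:
    """Clipped rectangular window sums of an integer array.

    Returns S[i, j] = sum of ``arr`` over rows [i-up, i+down] × cols
    [j-left, j+right] intersected with the array extent, for every (i, j)
    in ``out_shape`` (``arr`` may be smaller than ``out_shape`` — indexes
    outside contribute nothing, which is how pair grids are handled).
    """
    nr, nc = arr.shape
    ii = np.zeros((nr + 1, nc + 1), dtype=np.int64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    rows = np.arange(out_shape[0])[:, None]
    cols = np.arange(out_shape[1])[None, :]
    r0 = np.broadcast_to(np.clip(rows - up, 0, nr), out_shape)
    r1 = np.broadcast_to(np.clip(rows + down + 1, 0, nr), out_shape)
    c0 = np.broadcast_to(np.clip(cols - left, 0, nc), out_shape)
    c1 = np.broadcast_to(np.clip(cols + right + 1, 0, nc), out_shape)
    return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]


def _density_counts(fm: ForestMask, window: int):
    """(N_f, N_w): valid-forest and valid pixel counts per centered window."""
    k = _check_window(window) // 2
    forest = ((fm.mask == 1) & fm.valid_mask).astype(np.int64)
    valid = fm.valid_mask.astype(np.int64)
    nf = _windowed_sum(forest, k, k, k, k, fm.shape)
    nw = _windowed_sum(valid, k, k, k, k, fm.shape)
    return nf, nw


def _pair_counts(fm: ForestMask, window: int):
    """(D_both, D_any): both-forest and ≥1-forest valid pair counts per window.

    Horizontal pairs are indexed by their left pixel, vertical pairs by
    their top pixel; a pair is inside the window centered at (i, j) iff
    both its pixels are, which shrinks the pair window by one along the
    pair axis.
    """
    k = _check_window(window) // 2
    f = (fm.mask == 1) & fm.valid_mask
    v = fm.valid_mask

    h_valid = v[:, :-1] & v[:, 1:]
    h_both = (f[:, :-1] & f[:, 1:] & h_valid).astype(np.int64)
    h_any = ((f[:, :-1] | f[:, 1:]) & h_valid).astype(np.int64)
    v_valid = v[:-1, :] & v[1:, :]
    v_both = (f[:-1, :] & f[1:, :] & v_valid).astype(np.int64)
    v_any = ((f[:-1, :] | f[1:, :]) & v_valid).astype(np.int64)

    d_both = _windowed_sum(h_both, k, k, k, k - 1, fm.shape) + _windowed_sum(
        v_both, k, k - 1, k, k, fm.shape
    )
    d_any = _windowed_sum(h_any, k, k, k, k - 1, fm.shape) + _windowed_sum(
        v_any, k, k - 1, k, k, fm.shape
    )
    return d_both, d_any


def forest_density(fm: ForestMask, window: int) -> np.ndarray:
    """Pf grid: in-window forest fraction; NaN where no valid pixel in window."""
    nf, nw = _density_counts(fm, window)
    pf = np.full(fm.shape, np.nan)
    np.divide(nf, nw, out=pf, where=nw > 0)
    return pf


def forest_connectivity(fm: ForestMask, window: int) -> np.ndarray:
    """Pff grid: both-forest / ≥1-forest pair ratio; NaN where undefined."""
    d_both, d_any = _pair_counts(fm, window)
    pff = np.full(fm.shape, np.nan)
    np.divide(d_both, d_any, out=pff, where=d_any > 0)
    return pff


def classify_fragmentation(pf: float, pff: float | None, eps: float = 1e-9) -> str:
    """Assign the fragmentation category for one (Pf, Pff) value pair.

    ``pff`` may be None or NaN (no qualifying pair in the window); with
    Pf > 0.6 such a pixel is reported "undetermined". The tolerance guards
    float-rounded inputs; the gridded path compares exact integer counts
    instead.
    """
    if not 0.0 <= pf <= 1.0:
        raise ValueError(f"Pf must lie in [0, 1], got {pf}")
    pff_undef = pff is None or np.isnan(pff)
    if not pff_undef and not 0.0 <= pff <= 1.0:
        raise ValueError(f"Pff must lie in [0, 1], got {pff}")
    if pf >= 1.0 - eps:
        return "interior"
    if pf < 0.4:
        return "patch"
    if pf <= 0.6:
        return "transitional"
    if pff_undef or abs(pf - pff) <= eps:
        return "undetermined"
    return "perforated" if pf > pff else "edge"


def fragment_map(fm: ForestMask, window: int) -> FragmentationGrid:
    """Compute Pf, Pff and the category grid for one window size.

    Categories are assigned only where the mask is forest; all other pixels
    (non-forest and nodata) are background. Category decisions use the raw
    integer counts, so boundary cases (Pf = 1, Pf = Pff) are exact.
    """
    window = _check_window(window)
    nf, nw = _density_counts(fm, window)
    d_both, d_any = _pair_counts(fm, window)

    pf = np.full(fm.shape, np.nan)
    np.divide(nf, nw, out=pf, where=nw > 0)
    pff = np.full(fm.shape, np.nan)
    np.divide(d_both, d_any, out=pff, where=d_any > 0)

    cat = np.zeros(fm.shape, dtype=np.uint8)
    forest = (fm.mask == 1) & fm.valid_mask  # a forest pixel is always valid

    interior = forest & (nf == nw)
    patch = forest & ~interior & (5 * nf < 2 * nw)
    transitional = forest & ~interior & (5 * nf >= 2 * nw) & (5 * nf <= 3 * nw)
    dense = forest & ~interior & (5 * nf > 3 * nw)
    # cross-multiplied Pf vs Pff on exact counts; d_any == 0 → undetermined
    perforated = dense & (nf * d_any > d_both * nw)
    edge = dense & (nf * d_any < d_both * nw)
    undetermined = dense & ~perforated & ~edge

    cat[patch] = CATEGORY_CODES["patch"]
    cat[transitional] = CATEGORY_CODES["transitional"]
    cat[perforated] = CATEGORY_CODES["perforated"]
    cat[undetermined] = CATEGORY_CODES["undetermined"]
    cat[edge] = CATEGORY_CODES["edge"]
    cat[interior] = CATEGORY_CODES["interior"]
    return FragmentationGrid(pf=pf, pff=pff, category=cat, window=window,
                             transform=fm.transform)


def fragmentation_summary(fg: FragmentationGrid) -> pd.DataFrame:
    """Per-category pixel count, area (km²) and percent of forest area.

    Percentages are relative to the forest pixel count (the categories
    partition forest pixels), so they sum to 100.
    """
    forest_total = int((fg.category > 0).sum())
    if forest_total == 0:
        raise ValueError("fragmentation grid contains no forest pixels")
    px_km2 = (fg.transform.pixel_size_m ** 2) * 1e-6
    rows = []
    for code in range(1, 7):
        n = int((fg.category == code).sum())
        rows.append(
            {
                "category": CATEGORY_NAMES[code],
                "count": n,
                "km2": n * px_km2,
                "percent": 100.0 * n / forest_total,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["window"] = fg.window
    return df
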