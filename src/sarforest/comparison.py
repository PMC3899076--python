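"""Cross-product comparison of forest maps and area tables.

Fine-resolution forest masks are block-aggregated to fractional-cover
grids on a common coarse cell (1.5 km by default — the lowest common
multiple of 50-m, 300-m and 500-m pixels), differenced cell-by-cell, and
summarized as binned histograms. Per-region forest areas from different
products are compared with the root-mean-square deviation (RMSD) and a
least-squares regression forced through the origin (slope = Σxy/Σx²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragmentation import ForestMask
from .grids import GridTransform

__all__ = [
    "FractionGrid",
    "AreaTable",
    "aggregate_fraction",
    "difference_map",
    "rmsd",
    "fit_through_origin",
    "regional_areas",
]

# default ±30-point emphasis band plus open tails, mirroring the usual
# fractional-difference reporting convention
DEFAULT_BINS = (-100.0, -60.0, -30.0, -10.0, 0.0, 10.0, 30.0, 60.0, 100.0)


@dataclass
class FractionGrid:
    """Coarse-cell forest fraction with per-cell contributing-pixel counts."""

    fraction: np.ndarray
    n_valid: np.ndarray
    cell_size_m: float = 1500.0
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self):
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.n_valid = np.asarray(self.n_valid, dtype=np.int64)
        ok = self.n_valid > 0
        f = self.fraction[ok]
        if f.size and (np.nanmin(f) < 0 or np.nanmax(f) > 1):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def shape(self):
        return self.fraction.shape


@dataclass
class AreaTable:
    """Per-region forest areas in 10³ km² for one map product."""

    table: pd.DataFrame  # columns: region_id, region_name, area_1e3km2
    source: str = ""

    def __post_init__(self):
        required = {"region_id", "region_name", "area_1e3km2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"AreaTable missing columns: {sorted(missing)}")
        if (self.table["area_1e3km2"] < 0).any():
            raise ValueError("areas must be non-negative")

    def areas_by_id(self) -> pd.Series:
        return self.table.set_index("region_id")["area_1e3km2"]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["source"] = self.source
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source: str | None = None) -> "AreaTable":
        df = pd.read_csv(path)
        src = source if source is not None else str(df.get("source", pd.Series([""])).iloc[0])
        return cls(table=df[["region_id", "region_name", "area_1e3km2"]], source=src)


def aggregate_fraction(fm: ForestMask, factor: int = 30) -> FractionGrid:
    """Block-average a fine forest mask to a coarse fractional-cover grid.

    Each coarse cell covers a ``factor`` × ``factor`` block of fine pixels;
    its fraction is forest pixels / *valid* pixels in the block (NaN when
    the block is all nodata). Trailing rows/columns that do not fill a
    whole block are dropped.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    nr, nc = fm.shape
    br, bc = nr // factor, nc // factor
    if br == 0 or bc == 0:
        raise ValueError(f"factor {factor} exceeds raster shape {fm.shape}")
    forest = ((fm.mask == 1) & fm.valid_mask).astype(np.int64)
    valid = fm.valid_mask.astype(np.int64)

    def block_sum(a):
        return a[: br * factor, : bc * factor].reshape(br, factor, bc, factor).sum(axis=(1, 3))

    nf = block_sum(forest)
    nv = block_sum(valid)
    frac = np.full((br, bc), np.nan)
    np.divide(nf, nv, out=frac, where=nv > 0)
    t = fm.transform
    coarse = GridTransform(t.x0, t.y0, t.pixel_size_m * factor)
    return FractionGrid(fraction=frac, n_valid=nv, cell_size_m=t.pixel_size_m * factor,
                        transform=coarse)


def difference_map(a: FractionGrid, b: FractionGrid, bins=DEFAULT_BINS,
                   min_valid_share: float = 0.5):
    """Cell-wise (a − b)·100 percentage-point difference plus its histogram.

    Cells where either grid has fewer than ``min_valid_share`` of its fine
    pixels observed are excluded (NaN). Returns ``(diff_grid, histogram)``
    where the histogram DataFrame carries the bin edges, counts, and the
    share of compared cells whose difference lies within ±30 points.
    """
    if a.shape != b.shape or a.cell_size_m != b.cell_size_m:
        raise ValueError("fraction grids must share geometry")
    full = np.maximum(a.n_valid.max(initial=0), b.n_valid.max(initial=0))
    ok = (
        (a.n_valid >= min_valid_share * full)
        & (b.n_valid >= min_valid_share * full)
        & np.isfinite(a.fraction)
        & np.isfinite(b.fraction)
    )
    diff = np.full(a.shape, np.nan)
    diff[ok] = (a.fraction[ok] - b.fraction[ok]) * 100.0
    vals = diff[ok]
    edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    hist.attrs["n_cells"] = int(vals.size)
    hist.attrs["share_within_30"] = (
        float(np.mean(np.abs(vals) <= 30.0)) * 100.0 if vals.size else float("nan")
    )
    return diff, hist


def rmsd(a: AreaTable, b: AreaTable) -> float:
    """Root-mean-square deviation of per-region areas, matched by region id."""
    sa, sb = a.areas_by_id(), b.areas_by_id()
    unmatched = sorted(set(sa.index) ^ set(sb.index))
    if unmatched:
        raise ValueError(f"regions present in only one table: {unmatched}")
    d = sa - sb.reindex(sa.index)
    return float(np.sqrt(np.mean(np.square(d.to_numpy(dtype=float)))))


def fit_through_origin(x, y):
    """Least-squares line through the origin: slope = Σxy/Σx².

    Returns ``(slope, r2)`` with R² = 1 − Σ(y − bx)² / Σ(y − ȳ)² (NaN when
    y is constant). Raises on fewer than two points or all-zero x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all x are zero; slope through origin undefined")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return slope, r2


def regional_areas(fm: ForestMask, regions: np.ndarray,
                   region_names: dict | None = None, source: str = "") -> AreaTable:
    """Tabulate forest area per region from a co-registered region raster.

    ``regions`` holds positive integer region ids (0 = outside). Areas are
    forest-pixel count × pixel area, reported in 10³ km².
    """
    regions = np.asarray(regions)
    if regions.shape != fm.shape:
        raise ValueError("region raster must be co-registered with the mask")
    ids = np.unique(regions[regions > 0])
    if ids.size == 0:
        raise ValueError("region layer is empty")
    px_1e3km2 = (fm.pixel_size_m ** 2) * 1e-6 * 1e-3
    forest = (fm.mask == 1) & fm.valid_mask
    rows = []
    for rid in ids:
        n = int((forest & (regions == rid)).sum())
        name = (region_names or {}).get(int(rid), str(int(rid)))
        rows.append({"region_id": int(rid), "region_name": name,
                     "area_1e3km2": n * px_1e3km2})
    return AreaTable(table=pd.DataFrame(rows), source=source)
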