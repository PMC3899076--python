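"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's input surface:

* class mosaics — spatially autocorrelated categorical landscapes hit the
  requested class fractions by thresholding a smoothed Gaussian random
  field at its empirical quantiles;
* dual-pol scenes — per-pixel (HH, HV) backscatter drawn from per-class
  Gaussians *in dB space* (the standard log-normal texture approximation
  for multi-looked SAR power), then inverted through the calibration
  equation to integer digital numbers, exactly as the mosaic product
  stores them;
* binary forest landscapes — thresholded smoothed fields with tunable
  cover and clustering radius, feeding the fragmentation model.

Default class signatures sit at the centers of the decision-tree threshold
boxes (water −20/−27, forest −6/−11, cropland −11/−18, other −5/−6 dB for
HH/HV), so a small per-class spread keeps nearly every pixel inside its
generating class's box. Corner-reflector effects of real built-up areas
are not modeled. Everything is driven by an explicit seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box

from .accuracy import ROISet
from .calibration import DEFAULT_CF, invert_db_to_dn
from .classify import CLASS_CODES
from .fragmentation import ForestMask
from .grids import DualPolScene, GridTransform

__all__ = [
    "ClassSignature",
    "DEFAULT_SIGNATURES",
    "LandscapeSpec",
    "generate_class_mosaic",
    "generate_scene",
    "generate_forest_landscape",
    "generate_rois",
]


@dataclass(frozen=True)
class ClassSignature:
    """Mean (HH, HV) backscatter in dB and per-class spread for one class."""

    label: str
    mean_hh: float
    mean_hv: float
    sd: float = 0.3

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("signature sd must be > 0")


DEFAULT_SIGNATURES = {
    "water": ClassSignature("water", -20.0, -27.0),
    "forest": ClassSignature("forest", -6.0, -11.0),
    "cropland": ClassSignature("cropland", -11.0, -18.0),
    "other": ClassSignature("other", -5.0, -6.0),
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Shape, class fractions, patch scale and seed for a synthetic mosaic."""

    shape: tuple = (200, 200)
    fractions: dict = field(
        default_factory=lambda: {"water": 0.1, "forest": 0.5, "cropland": 0.3, "other": 0.1}
    )
    patch_scale: float = 3.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must be >= 0 and sum to 1")
        unknown = set(self.fractions) - (set(CLASS_CODES) - {"nodata"})
        if unknown:
            raise ValueError(f"unknown classes in fractions: {sorted(unknown)}")


def _smooth_field(shape, scale, rng) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if scale > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=scale, mode="reflect")
    # tiny jitter breaks ties so quantile thresholds land exact fractions
    field_ += rng.uniform(-1e-9, 1e-9, size=shape)
    return field_


def generate_class_mosaic(spec: LandscapeSpec) -> np.ndarray:
    """Categorical landscape matching the requested fractions within ±0.02.

    One smoothed Gaussian field is cut at its empirical quantiles, so each
    class occupies a contiguous value band — classes form patches whose
    size grows with ``patch_scale``.
    """
    rng = np.random.default_rng(spec.seed)
    field_ = _smooth_field(spec.shape, spec.patch_scale, rng)
    order = [c for c in ("water", "forest", "cropland", "other") if spec.fractions.get(c, 0) > 0]
    fracs = np.array([spec.fractions[c] for c in order])
    edges = np.quantile(field_, np.cumsum(fracs)[:-1]) if len(order) > 1 else []
    bands = np.digitize(field_, edges)
    grid = np.zeros(spec.shape, dtype=np.uint8)
    for i, cname in enumerate(order):
        grid[bands == i] = CLASS_CODES[cname]
    realized = np.bincount(grid.ravel(), minlength=5) / grid.size
    for cname in order:
        if abs(realized[CLASS_CODES[cname]] - spec.fractions[cname]) > 0.02:
            raise ValueError(
                f"could not realize fraction for {cname}: wanted "
                f"{spec.fractions[cname]:.3f}, got {realized[CLASS_CODES[cname]]:.3f}"
            )
    return grid


def generate_scene(class_grid: np.ndarray, signatures: dict | None = None,
                   cf=DEFAULT_CF, seed: int = 0, sd: float | None = None,
                   transform: GridTransform | None = None):
    """Draw a dual-pol DN scene from per-class Gaussian dB signatures.

    Per pixel, (HH, HV) dB values are drawn independently from the class's
    Gaussian, inverted through the calibration equation and rounded to the
    nearest positive integer DN (floor 1 — DN 0 is reserved for nodata).
    Returns ``(scene, truth)`` where ``truth`` is the generating class grid.
    Pixels with class 0 in ``class_grid`` become nodata (DN 0).
    """
    class_grid = np.asarray(class_grid)
    signatures = dict(signatures or DEFAULT_SIGNATURES)
    if sd is not None:
        signatures = {
            k: ClassSignature(s.label, s.mean_hh, s.mean_hv, sd) for k, s in signatures.items()
        }
    present = set(np.unique(class_grid)) - {0}
    missing = [c for c in present if (lbl := {v: k for k, v in CLASS_CODES.items()}[c]) not in signatures]
    if missing:
        raise ValueError(f"no signature for class code(s) {missing}")
    rng = np.random.default_rng(seed)
    hh_db = np.zeros(class_grid.shape)
    hv_db = np.zeros(class_grid.shape)
    for label, sig in signatures.items():
        sel = class_grid == CLASS_CODES[label]
        n = int(sel.sum())
        if n == 0:
            continue
        hh_db[sel] = rng.normal(sig.mean_hh, sig.sd, n)
        hv_db[sel] = rng.normal(sig.mean_hv, sig.sd, n)
    valid = class_grid > 0
    hh_dn = np.where(valid, np.maximum(np.rint(invert_db_to_dn(hh_db, cf)), 1), 0)
    hv_dn = np.where(valid, np.maximum(np.rint(invert_db_to_dn(hv_db, cf)), 1), 0)
    scene = DualPolScene(
        hh_dn=hh_dn.astype(np.int64),
        hv_dn=hv_dn.astype(np.int64),
        transform=transform or GridTransform(),
    )
    return scene, class_grid.astype(np.uint8)


def generate_forest_landscape(shape, cover: float, clustering: float = 0.0,
                              seed: int = 0,
                              transform: GridTransform | None = None) -> ForestMask:
    """Binary forest mask with target cover and tunable spatial clustering.

    A Gaussian field smoothed with sigma = ``clustering`` is thresholded at
    its (1 − cover) empirical quantile, so realized cover matches the
    target to well within ±0.02; larger clustering radii produce blobbier
    forest and hence higher connectivity (Pff) at fixed cover.
    """
    if not 0.0 <= cover <= 1.0:
        raise ValueError("cover must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if cover in (0.0, 1.0):
        mask = np.full(shape, int(cover), dtype=np.int8)
    else:
        field_ = _smooth_field(shape, clustering, rng)
        thr = np.quantile(field_, 1.0 - cover)
        mask = (field_ > thr).astype(np.int8)
    return ForestMask(mask=mask, transform=transform or GridTransform())


def generate_rois(class_grid: np.ndarray, n_per_class: int = 3, min_pixels: int = 6,
                  seed: int = 0, transform: GridTransform | None = None) -> ROISet:
    """Rectangular single-class ROIs, each at least ``min_pixels`` pixels.

    The default floor of 6 pixels honors a 3 × 0.5-ha minimum mapping unit
    at 50-m pixels (0.25 ha each). Rectangles are aligned to pixel edges
    inside homogeneous areas, so rasterizing them back is 100% pure by
    construction. Raises naming the class when no sufficiently large
    homogeneous rectangle exists for a class present in the grid.
    """
    class_grid = np.asarray(class_grid)
    transform = transform or GridTransform()
    rng = np.random.default_rng(seed)
    # smallest rectangle with >= min_pixels: near-square footprint
    h = int(np.floor(np.sqrt(min_pixels)))
    w = int(np.ceil(min_pixels / h))
    px = transform.pixel_size_m
    polys = []
    for code in sorted(set(np.unique(class_grid)) - {0}):
        label = {v: k for k, v in CLASS_CODES.items()}[int(code)]
        is_class = (class_grid == code).astype(np.int64)
        # top-left corners where an h×w block is single-class: the block
        # sum (via an integral image) must equal the block area
        ii = np.zeros((is_class.shape[0] + 1, is_class.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(is_class, axis=0), axis=1, out=ii[1:, 1:])
        block = ii[h:, w:] - ii[:-h, w:] - ii[h:, :-w] + ii[:-h, :-w]
        anchors = np.argwhere(block == h * w)
        if len(anchors) == 0:
            raise ValueError(
                f"class {label!r} has no homogeneous {h}x{w} block for an ROI"
            )
        # greedy non-overlapping selection from a shuffled anchor list
        order = rng.permutation(len(anchors))
        taken = np.zeros(class_grid.shape, dtype=bool)
        picks = []
        for idx in order:
            r, c = anchors[idx]
            if taken[r:r + h, c:c + w].any():
                continue
            taken[r:r + h, c:c + w] = True
            picks.append((r, c))
            if len(picks) >= n_per_class:
                break
        for i, (r, c) in enumerate(picks):
            geom = box(
                transform.x0 + c * px,
                transform.y0 - (r + h) * px,
                transform.x0 + (c + w) * px,
                transform.y0 - r * px,
            )
            polys.append((geom, label, f"{label}_{i}"))
    return ROISet(polygons=polys)
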