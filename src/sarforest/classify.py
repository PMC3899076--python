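"""Threshold decision-tree land-cover classification of dual-pol backscatter.

Four broad classes are mapped from HH, HV, the HH−HV difference and the
HH/HV ratio (all on dB values), with rules applied in a fixed precedence
order — water, forest, cropland, then everything else:

* water:    HH < −16 dB and HV < −24 dB
* forest:   3.5 < HH−HV < 6.5 dB, −15 < HV < −7 dB, 0.3 < ratio < 0.7
* cropland: HV < −16 dB
* other:    any remaining valid pixel (built-up land, shrubs, ...)

All inequalities are strict; a boundary-equal pixel falls through to the
next rule. The upper difference bound doubles as an oil-palm guard: palm
canopies push HH−HV above 6.5 dB and are deliberately excluded from forest.
Pixels whose ratio is undefined (HV = 0 dB) skip the forest rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .grids import BackscatterStack, GridTransform

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "RuleSet",
    "LandCoverGrid",
    "classify_pixel",
    "classify_scene",
    "to_forest_mask",
]

CLASS_CODES = {"nodata": 0, "water": 1, "forest": 2, "cropland": 3, "other": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass(frozen=True)
class RuleSet:
    """Decision-tree thresholds (dB except the unitless ratio bounds).

    The defaults are the published continental thresholds for the 50-m
    L-band mosaic; any of them can be overridden, e.g. from a YAML profile.
    """

    water_hh_max: float = -16.0
    water_hv_max: float = -24.0
    forest_diff_min: float = 3.5
    forest_diff_max: float = 6.5
    forest_hv_min: float = -15.0
    forest_hv_max: float = -7.0
    forest_ratio_min: float = 0.3
    forest_ratio_max: float = 0.7
    cropland_hv_max: float = -16.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"threshold {name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        return cls(**d)


@dataclass
class LandCoverGrid:
    """Per-pixel categorical land-cover map.

    Codes: 0 nodata, 1 water, 2 forest, 3 cropland, 4 other.
    """

    classes: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    class_legend: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.max(initial=0) > 4:
            raise ValueError("class codes must lie in 0..4")

    @property
    def shape(self):
        return self.classes.shape

    def class_counts(self) -> dict:
        counts = np.bincount(self.classes.ravel(), minlength=5)
        return {self.class_legend[c]: int(counts[c]) for c in range(5)}


def classify_pixel(hh, hv, diff, ratio, rules: RuleSet = RuleSet()) -> int:
    """Classify one pixel; first matching rule in precedence order wins.

    ``ratio`` may be NaN (undefined); the pixel then cannot be forest.
    Returns the integer class code.
    """
    if hh < rules.water_hh_max and hv < rules.water_hv_max:
        return CLASS_CODES["water"]
    if (
        not np.isnan(ratio)
        and rules.forest_diff_min < diff < rules.forest_diff_max
        and rules.forest_hv_min < hv < rules.forest_hv_max
        and rules.forest_ratio_min < ratio < rules.forest_ratio_max
    ):
        return CLASS_CODES["forest"]
    if hv < rules.cropland_hv_max:
        return CLASS_CODES["cropland"]
    return CLASS_CODES["other"]


def classify_scene(stack: BackscatterStack, rules: RuleSet = RuleSet()) -> LandCoverGrid:
    """Vectorized per-pixel decision tree over a backscatter stack.

    Invalid pixels map to nodata (0). Every valid pixel receives exactly
    one of the four class codes, so the class counts partition the valid
    pixel count.
    """
    hh, hv, diff, ratio = stack.hh_db, stack.hv_db, stack.diff_db, stack.ratio
    valid = stack.valid_mask
    out = np.zeros(stack.shape, dtype=np.uint8)

    water = valid & (hh < rules.water_hh_max) & (hv < rules.water_hv_max)
    forest = (
        valid
        & ~water
        & stack.ratio_valid
        & (diff > rules.forest_diff_min)
        & (diff < rules.forest_diff_max)
        & (hv > rules.forest_hv_min)
        & (hv < rules.forest_hv_max)
        & (ratio > rules.forest_ratio_min)
        & (ratio < rules.forest_ratio_max)
    )
    cropland = valid & ~water & ~forest & (hv < rules.cropland_hv_max)
    other = valid & ~water & ~forest & ~cropland

    out[water] = CLASS_CODES["water"]
    out[forest] = CLASS_CODES["forest"]
    out[cropland] = CLASS_CODES["cropland"]
    out[other] = CLASS_CODES["other"]
    return LandCoverGrid(classes=out, transform=stack.transform)


def to_forest_mask(lc: LandCoverGrid):
    """Collapse a land-cover map to forest(1)/non-forest(0); nodata → −1.

    Returns ``(mask, valid)`` where ``mask`` is int8 with −1 at nodata and
    ``valid`` the boolean observed-pixel mask.
    """
    valid = lc.classes != CLASS_CODES["nodata"]
    mask = np.full(lc.shape, -1, dtype=np.int8)
    mask[valid] = 0
    mask[lc.classes == CLASS_CODES["forest"]] = 1
    return mask, valid
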