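# Methods

## Scope and data model

All rasters are row-major numpy grids with square pixels, origin at the
top-left corner, pixel-is-area convention; georeferencing is a local
affine (`x0`, `y0`, pixel size in metres, default 50 m). Rasters are
stored as plain TIFF with the transform, nodata value and band names in a
JSON document inside the ImageDescription tag; reference polygons travel
as GeoJSON with the class label in a `class` property; matrices and area
tables as CSV. No projection handling is attempted: inputs are assumed
co-registered on a common grid, which is the situation for an
already-orthorectified mosaic product and for everything derived from it.

## Calibration

σ⁰ = 10·log₁₀(DN²) + CF, CF = −83 dB. DN = 0 is mosaic fill and becomes
nodata, never −∞ dB; negative DN is rejected as corrupt input. The
inverse DN = 10^((σ⁰ − CF)/20) is exact, so the round trip is
machine-precision (asserted at ≤ 1e−9 dB). Two derived bands accompany
the calibrated channels: the difference HH − HV in dB and the ratio
HH/HV computed **on the dB values**, not on linear power. The dB reading
is a deliberate design choice: only then does the forest ratio box
0.3–0.7 cohere with the dB boxes (HH = −6, HV = −11 gives 0.545; the
linear-power ratio would be ≈ 3.2). The ratio is undefined where HV is
exactly 0 dB; such pixels carry an invalid-ratio flag, are excluded from
the forest rule and fall through to the remaining rules — 0 dB lies
outside every class box, so nothing is lost.

## Classification

The decision tree applies four rules in a fixed precedence — water,
forest, cropland, other. Precedence matters because the boxes overlap
(HV = −25 dB satisfies both the water and cropland conditions); listing
order resolves it. All inequalities are strict; a pixel exactly on a
boundary falls through to the next rule. The forest rule is the
conjunction of all three conditions (difference, HV, ratio). "Other"
aggregates built-up land, shrubs and all remainder. Thresholds live in a
`RuleSet` dataclass serializable to YAML, so the published operating
point ships as the default profile and any threshold can be audited or
overridden without touching code. The pipeline log header records the
rule order and the Pff orientation (below) on every run, since both are
places where reasonable implementations could differ.

## Accuracy assessment

ROIs are rasterized with the pixel-center-in-polygon rule (standard,
unambiguous under the pixel-is-area convention); overlapping polygons
resolve to the last listed, with a warning. The confusion matrix is
predicted × reference over jointly labeled pixels; pixels lacking either
label — including map nodata — are excluded rather than counted as a
class. Producer's accuracy is the diagonal over the reference-column
total, user's over the predicted-row total, overall the trace over the
grand total; classes absent from reference or prediction report NaN
rather than an arbitrary 0 or 100. The packaged continental validation
matrix has one empty cell (water predicted, "others" reference), read as
zero — the printed row and column totals confirm that reading. Reported
accuracies round to integer percent to match the table's precision; full
precision is retained internally.

## Fragmentation

Pf and Pff follow the Riitters moving-window model. One published
formulation inverts the Pff quotient (pairs touching forest over
both-forest pairs), which can exceed 1; this package implements the
standard conditional-probability orientation, both-forest pairs over
pairs with at least one forest pixel, bounded by [0, 1]. Pairs are
cardinal neighbours fully inside the window. Windows are truncated at
raster borders and around nodata — denominators count only valid pixels
and valid pairs, so border pixels get honest (smaller-sample) estimates
rather than padded ones.

Both indices are computed as exact integer counts via integral images
(identical to the naive double loop, asserted against it in tests), and
category decisions compare those counts by cross-multiplication, so
Pf = 1 and Pf = Pff are decided exactly. The scalar
`classify_fragmentation` entry point accepts float inputs and uses a
1e−9 tolerance instead. Category assignment order: interior (Pf = 1)
first — otherwise Pf = 1 ⇒ Pff = 1 would land in "undetermined" — then
patch (Pf < 0.4), transitional (0.4 ≤ Pf ≤ 0.6; the boundary values are
unassigned by the strict published criteria and are folded in here so
the categories partition [0, 1]), then perforated / undetermined / edge
by the sign of Pf − Pff. A Pff undefined above Pf = 0.6 (possible only
for isolated valid pixels amid nodata) reports "undetermined".
Categories are assigned per forest pixel and summary percentages are
relative to forest area; they sum to 100 by construction. Window sizes
default to 9, 21 and 101 pixels (450 m, 1050 m, 5050 m at 50-m pixels).
Interior share is scale-dependent — non-increasing in window size on
nested windows — and the tests assert that property on synthetic
landscapes; continental-scale category percentages require the real
mosaic and are outside what synthetic tests can show.

## Product comparison

Masks aggregate to fractional cover by factor×factor block averaging
(default 30: 50 m → 1.5 km, the least common multiple of 50-m, 300-m and
500-m products); the denominator is the count of valid fine pixels per
block and trailing partial blocks are dropped, so Σ(fraction × n_valid)
equals the fine forest count on divisible rasters. Difference maps are
(a − b)·100 percentage points; cells with under 50% valid fine pixels in
either product are excluded — the choice made for partially observed
cells (e.g. a mosaic gap) since no published convention exists.
Histogram bins emphasise the ±30-point band and the share within it is
reported. Area tables are compared by RMSD over regions matched by id
(unmatched regions are an error listing them), and by least-squares
regression through the origin, slope = Σxy/Σx², with
R² = 1 − SS_res/SS_tot. RMSD on the packaged national table is reported
rounded to integer 10³ km² to match the table's precision. "Mainland"
means Myanmar, Thailand, Laos, Vietnam and Cambodia; that five-country
set reproduces the published mainland RMSDs exactly. The Indonesian SAR
area is the sum of the observed part and the MODIS-filled complement
(885 + 419), kept as separate CSV columns and summed on load. Class maps
from other products enter only through a user-supplied
code → forest/non-forest reclassification, not shipped legends.

## Synthetic data

Backscatter is modeled Gaussian in dB (log-normal in power), the usual
approximation for multi-looked SAR texture; no published distributions
exist for the class signatures, so the default means sit at the centers
of the threshold boxes (water −20/−27, forest −6/−11, cropland −11/−18,
other −5/−6 dB HH/HV) with a default spread of 0.3 dB — small enough
that ≥ 99% of pixels stay inside their generating box, which is the
label-recovery condition the tests assert. Real confounders —
corner-reflector returns from buildings, speckle correlation, terrain
and soil-moisture effects — are not modeled, so passing recovery tests
demonstrates the classifier's correctness, not its field accuracy.
Scenes are quantized to integer DN (nearest, floor 1); at forest levels
(−6 dB, DN ≈ 7080) one DN step is < 0.09 dB, bounded in tests.

Landscapes (categorical and binary) come from thresholding a
Gaussian-smoothed random field at empirical quantiles: realized class
fractions land within ±0.02 of target (asserted across 20 seeds) and the
smoothing radius controls patchiness — larger radius raises mean Pff at
fixed cover. Generated ROIs are pixel-aligned rectangles of at least 6
pixels (three times a 0.5-ha minimum mapping unit at 0.25 ha/pixel)
placed greedily without overlap inside single-class areas, so
rasterizing them back is pure by construction. All generators are
bit-reproducible from their seed.

## Problem sizes and numerical notes

Tests and the acceptance script run on 150–300-pixel-square synthetic
scenes: large enough for the 101-pixel window and 30× aggregation to be
meaningful, small enough to run in seconds. The fragmentation oracle
check compares against a pure-Python per-pixel enumeration on 30×30
masks for windows 3, 9 and 21. Integer window counts fit comfortably in
int64 (worst products ≈ 10⁴ × 2×10⁴). Deterministic outputs: identical
config and seed give identical grids; the pipeline writes a provenance
record (config digest, seed, version, rule order, Pff orientation) next
to its products.

## Known limitations

No orthorectification, speckle filtering, terrain correction or
projection handling — inputs are assumed already mosaicked and
co-registered. No threshold training from ROI statistics (thresholds are
fixed inputs). No kappa or area-weighted accuracy estimators. The
fragmentation "undetermined" category is rare on real-valued landscapes
but nonzero on exact counts (e.g. Pf = Pff in small windows). Fractional
comparison assumes both products share the coarse grid exactly.
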