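# Methods

## Overview

The package links three models: an image-analysis model that extracts
penguin-shadow pixels from aerial photographs, a photogrammetric model
that converts a shadow-pixel total into a bird count via solar geometry,
and a biogeochemical budget that converts the count into seasonal CH₄ and
N₂O emissions from the colony's guano. Each stage is usable on its own;
the pipeline module chains them deterministically.

## Shadow photogrammetry

The sun's zenith angle follows from spherical trigonometry,
`cos z = sin θ sin δ + cos θ cos δ cos ω`, with latitude θ signed (south
negative), solar declination δ supplied from a declination table for the
acquisition date (no ephemeris is computed), and hour angle ω = l_d − l
normalized to (−180°, 180°]. Elevation is α = 90° − z. A standing bird of
height H and chest width W then casts a ground shadow approximated as an
H/tan α × W rectangle, i.e. `p = (H/tan α)·W/R²` pixels at ground
resolution R. Defaults H = 53.5 cm and W = 20 cm are the midpoints of the
adult Adélie ranges (46–61 cm height, 15–25 cm chest width). At
α = 37.72° and R = 0.1 m this gives p = 13.83, reported as 13.8: per-bird
pixel counts are only meaningful to one decimal, and the census divides
the shadow-pixel total by the 1-decimal value before rounding to the
nearest bird. α must lie strictly inside (0°, 90°): at 90° there is no
shadow and below the horizon there is no image.

## OBIA extraction

**Segmentation.** Greedy pairwise region merging from single pixels:
always merge the adjacent pair (rook adjacency by default) with the
lowest cost, stop when the cheapest merge exceeds `scale²`. The cost is
the area-weighted increase in within-region intensity standard deviation,
`h = (n₁+n₂)σ₁₂ − n₁σ₁ − n₂σ₂`, the intensity-only form of the classical
multiresolution heterogeneity criterion. Costs are computed on 8-bit
digital numbers (canonical [0, 1] intensity × 255, configurable) so the
conventional scale value 15 for 8-bit aerial imagery applies unchanged;
multi-band scenes are collapsed to per-pixel mean intensity first, so one
rule set serves grayscale and RGB surveys. The implementation is a lazy
binary heap over a region-adjacency graph with union-find bookkeeping;
a full-recompute brute-force merger in the test suite verifies on 8×8
instances that every accepted merge is the current global minimum and
that final partitions agree exactly.

*Merge-cost inversions.* The accepted-cost sequence is **not** globally
non-decreasing: under pixel-adjacency constraints a merge can create a
cheaper candidate than itself, for the σ-form cost above and equally for
the Ward variance form (the "inversion" phenomenon documented for
connectivity-constrained agglomerative clustering). Empirically every
noisy 8×8 block instance shows inversions. Monotonicity holds on
piecewise-flat images, where zero-cost within-level merges precede
boundary merges, and the tests assert it exactly there.

**Classification.** Per-object brightness index
`BI = (μ_scene − μ_object)/σ_scene` (darkness in global-σ units) and mean
deviation index `MDI = MAD_object/MAD_scene` (homogeneity relative to the
scene); both defined as 0 on a uniform scene. Objects with `BI > 0` and
`MDI < 0.85` — dark and homogeneous, i.e. shadows on bright gravel — form
the shadow mask; both index definitions and thresholds are configurable.
Objects above 45 px (several times a single bird's ~14 px shadow) are
flagged for manual review; flagging only annotates and reports, with an
optional `drop_flagged` switch to emulate a reviewer rejecting them.

The `BI > 0` threshold is knife-edge by construction: it asks only
"darker than the scene mean". It is discriminative when shadows occupy a
non-negligible fraction of the evaluated scene (~5% or more), which pulls
the scene mean visibly below the gravel level; segmentation of pure noise
otherwise yields regions whose means straddle the scene mean (region
growing selects coherently dark patches), and the darker half passes the
rule. This matches how such rules are used operationally — on manually
cropped penguin-dense regions, not on featureless terrain — and the
synthetic study conditions below follow suit. On a featureless scene the
extraction can therefore return spurious small detections; a density
pre-screen is the operator's job, not this package's.

## Accuracy assessment

Predicted and reference masks are compared per pixel: TP = pred ∩ truth,
FP = pred \ truth, FN = truth \ pred, TN the remainder; precision
TP/(TP+FP), recall TP/(TP+FN), and `F_β = (1+β²)PR/(β²P+R)` with β = 1 by
default (precision and recall equally weighted). Undefined scores (no
predicted positives, or an empty reference) are returned as NaN with a
warning and excluded from summaries. Sample `F_β` values are rounded to
two decimals before averaging — the precision at which such scores are
tabulated, and the convention under which the per-image means reproduce
from their printed columns — then per-image means are averaged into the
overall score, reported as a percentage to one decimal.

## Greenhouse-gas budget

Per bird-day fresh guano is `G = M_C·D + D` grams, with dry rate
D = 84.5 g/day and moisture content M_C = 1.8572 (dry-weight basis).
Flux factors are midpoints of aerobic incubation ranges quoted on the
element basis — CH₄-C 38.22–219.60 and N₂O-N 0.45–0.74 μg kg⁻¹ h⁻¹ —
converted to gas mass. CH₄-C→CH₄ is ×16/12 (171.88 μg kg⁻¹ h⁻¹). For
N₂O the package defaults to ×44/14 ("paper" mode, 1.87 μg kg⁻¹ h⁻¹),
the factor under which published colony budgets of this kind are
internally consistent; the chemically standard ×44/28 ("strict",
0.935 μg kg⁻¹ h⁻¹) is one switch away. The same duality appears in the
GWP weights, kept exactly as used in such budgets:
`GWP = (F_CH₄/16)·44·25 + (F_N₂O/28)·44·298` (100-year horizon factors
25 and 298).

**Population series.** The December census N₀ anchors a 90-day series
N_t. The *average* method holds N_t ≡ N₀. The *fitting* method models
attendance in three stages: a linear ramp from 0 to the 2N₀ peak over
days 1–30 (both pair members ashore during arrival and laying), a linear
decline to N₀ by day 45 (females leave to forage), then constant N₀
(pair members alternate). The series is continuous at both boundaries
(2N₀ at t = 30, N₀ at t = 45).

**Seasonal total.** The default ("printed") formula is
`F = Σ_{t=1..T} t·N_t·G·10⁻³·f·24·10⁻⁹` kg. The day-index weight t makes
each term the daily emission of a linearly accumulating guano stock when
N_t is constant (Σt = T(T+1)/2, giving the closed form
`F = T(T+1)/2·N₀·G·f·24·10⁻¹²` that the tests verify to 10⁻⁹ relative).
For a non-constant series that identity breaks, so a *cumulative*
variant replacing t·N_t with the explicitly accumulated stock Σ_{s≤t} N_s
is provided; the two coincide exactly for constant series. Under the
printed formula the fitting series gives 76.86 kg CH₄ for N₀ = 17,120
(cumulative variant: 75.20 kg), about 9% above the average method —
published fitting-method tabulations of ~73.8 kg are not reproducible
from these formulas, so tabulated fitting values are treated purely as
comparison inputs, never as validation targets; the average-method
column reproduces to the printed cent. Relative deviation between the
methods is 100·|avg − fit|/fit (0 for an empty colony). The global
extrapolation multiplies the average-method GWP per censused pair by the
3.79 × 10⁶ breeding pairs estimated worldwide, reported in tonnes.

N_t is used as censused (pair) counts with the per-individual guano rate
G and no ×2 pair expansion, the convention under which the budget is
internally consistent with its census; chick guano and legacy guano from
previous seasons are excluded (short chick residency; old deposits are
implicitly represented in the incubation-core flux factors).

## Synthetic scenes

The generator emulates the one property downstream stages rely on: dark,
elongated, well-separated per-bird shadow footprints on bright gravel.
Footprints are H/tan α × W ground rectangles (inscribed-ellipse option
behind a flag) rasterized by pixel-centre inclusion at resolution R —
unbiased for the footprint area, as a 10× supersampling oracle in the
tests confirms — along a configurable azimuth (surveys rarely record
acquisition time, so azimuth is free and defaults to image-x). Placement
is rejection sampling with minimum centre spacing of one footprint
diagonal (footprints never merge), a density guard that rejects requests
whose exclusion discs exceed ~60% of the placeable area, and an attempt
budget of 1000·n before a placement error naming the achieved count.
Intensities: background 0.75, shadow 0.15, additive Gaussian noise
σ = 0.05 clipped to [0, 1] — a strong-contrast, moderately noisy scene
typical of sunlit gravel colonies; RGB scenes replicate the pattern with
small per-channel offsets. Everything derives from one seeded generator:
identical seeds give bit-identical scenes.

Not emulated: penumbra, sun glint, terrain shading, overlapping huddles,
textured gravel, or the birds' own bodies (the census counts shadow
pixels only). Passing tests therefore demonstrate the correctness of the
extraction-census chain under its own geometric model, not field
performance on real imagery, where contrast and clutter are harsher.

**Study conditions.** The parameter-recovery study runs 20 seeded scenes
of 100–500 birds at survey geometry (R = 0.1 m, α = 37.72°) and colony
density ~0.6 birds/m² — within the range of dense Adélie sub-colonies
and the regime the classification rule is built for (shadow fraction
~8–10%) — and requires the census to land within ±10% of truth in at
least 80% of runs. Scene sides are sized as √(n/0.6) metres so the
density, not the image size, is the controlled quantity.

## Numerical choices and edge cases

- Merge ties in segmentation resolve by heap order (cost, then region
  ids); random continuous intensities make exact ties measure-zero, and
  flat regions merge at cost 0 in any order with the same partition.
- `arccos` arguments are clamped to [−1, 1]; zenith/elevation never NaN.
- p is rounded to one decimal before the census division; the census
  rounds half-up to the nearest bird.
- Uniform scenes define BI = MDI = 0 (no global spread to normalize by).
- Population, guano and flux inputs must be non-negative; degenerate
  denominators (p ≤ 0, fitting total 0 with nonzero average, empty
  summaries) raise rather than silently propagate.
- Reports carry a config hash, package version and seed, but no
  timestamp: identical config + seed must produce byte-identical output.

## Known limitations

- Shadow overlap and huddling are not modelled; real dense aggregations
  under-count and were handled by manual interpretation in operational
  surveys.
- The BI > 0 rule presumes a shadow-bearing crop (see above).
- δ and ω are inputs, not computed from date/time.
- The budget is a potential, not a process model: flux factors are
  constant in time and temperature, and guano accumulates linearly with
  no decay.
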