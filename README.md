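# shadowcensus

Count breeding penguins from the shadows they cast in aerial survey
photographs, and turn the census into a breeding-season greenhouse-gas
budget for the colony.

At high southern latitudes the sun stays low, so a standing Adélie penguin
(*Pygoscelis adeliae*) casts a long, dark shadow that is far easier to
detect in 0.1 m aerial imagery than the bird itself. This package
implements that survey chain end to end, for polar ecologists and
remote-sensing analysts:

1. **OBIA extraction** — multiresolution-style region merging segments the
   image into objects (greedy lowest-cost merging of adjacent regions,
   cost `h = (n₁+n₂)·σ₁₂ − n₁·σ₁ − n₂·σ₂`, stopping at `scale²`); objects
   that are darker than the scene (brightness index `BI > 0`) and
   internally homogeneous (mean deviation index `MDI < 0.85`) are
   classified as penguin shadow; objects over 45 px are flagged for
   manual review.
2. **Shadow photogrammetry** — solar elevation `α = 90° − z` with
   `cos z = sin θ sin δ + cos θ cos δ cos ω` (latitude θ, declination δ,
   hour angle ω = l_d − l); mean shadow pixels per bird
   `p = (H / tan α) · W / R²` for bird height `H`, chest width `W` and
   ground resolution `R`; census = total shadow pixels / `p`.
3. **Accuracy assessment** — pixel-set confusion counts (TP/FP/FN/TN) and
   precision / recall / `F_β` against reference masks, with per-image and
   overall means.
4. **GHG budget** — fresh guano `G = M_C·D + D` per bird-day, flux factors
   from incubation-range midpoints (μg CH₄ / N₂O per kg fresh guano per
   hour), seasonal emission
   `F = Σ_{t=1..90} t·N_t·G·10⁻³·f·24·10⁻⁹` kg under a constant
   ("average") or piecewise-linear attendance ("fitting") population
   series, and `GWP = (F_CH₄/16)·44·25 + (F_N₂O/28)·44·298` kg CO₂-eq.
5. **Synthetic scenes** — a seeded generator renders colonies of
   rectangular shadow footprints with exact truth masks and counts, so
   the whole chain is testable without survey imagery.

## Worked example

Census the colony from the two documented shadow-pixel totals and budget
its season:

```bash
$ penguin-pipeline census --pixels 236253 --p 13.8
{"pixels": 236253, "p": 13.8, "population": 17120}

$ penguin-pipeline ghg --population 17120 --method both
{"population": 17120,
 "average": {"F_ch4_kg": 69.82, "F_n2o_kg": 0.76, "gwp_kg": 5155.98},
 "fitting": {"F_ch4_kg": 76.86, "F_n2o_kg": 0.84, "gwp_kg": 5675.57},
 "summary": {..., "global_gwp_tonnes": 1141.42}}
```

(output abbreviated to 2 decimals). Reading: 236,253 shadow pixels at
13.8 px per bird is a December census of 17,120 breeding pairs; over a
90-day season those pairs excrete guano that emits ~70 kg CH₄ and
~0.8 kg N₂O, a global-warming potential of ~5.2 t CO₂-eq — and scaled to
the 3.79 million Adélie pairs worldwide, ~1141 t CO₂-eq per season.
The `fitting` figures use the three-stage attendance model evaluated
with the same seasonal formula (see `docs/methods.md` for why they
differ from the average-method values by ~9%).

A fully synthetic run — generate a 300-bird colony scene, extract, census,
score, budget:

```bash
$ penguin-pipeline run --config examples/synthetic_colony.yaml --out-dir out/
{"sun_elevation_deg": 37.72, "pixels_per_penguin": 13.8,
 "population": 303, "truth_count": 300, "out_dir": "out"}
```

The extracted mask scores precision 0.991 / recall 1.000 against the
generator's truth, and the census recovers the true 300 birds within 1%.
`out/` holds the scene PNG, shadow mask, object table, truth layout
(GeoJSON + CSV) and a deterministic JSON report.

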