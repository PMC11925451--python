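# v2lamina

Columnar and laminar fMRI analysis of early visual cortex, rebuilt as a
tested, reusable Python pipeline and driven by a synthetic BOLD generator
that plants every structure the analysis assumes.

## Who this is for

Laminar-fMRI methodologists and visual neuroscientists who want to (a)
analyse depth-resolved block-design data — stripe-shaped columnar maps in
V2, cortical-depth selectivity profiles, test–retest pattern reliability,
layer-specific informational connectivity — with a single reproducible
toolchain, and (b) validate that toolchain against ground truth, because
every analysis stage here can be run on synthetic cortices where the
"right answer" is planted and known.

## What it computes

* **Selectivity index.** For a condition pair (A, B) with ROI-averaged GLM
  responses β_A, β_B:  `SI = (β_A − β_B) / (β_A + β_B)` — e.g.
  SI_color = (β_chr − β_ach)/(β_chr + β_ach) for chromatic vs achromatic
  gratings, and likewise for disparity (3D vs 2D random-dot stereograms)
  and naturalistic texture vs spectrally matched noise.
* **Equi-volume cortical depth.** With local inner/outer surface-area
  elements A_in, A_out, the depth enclosing volume fraction α is
  `ρ = (−A_in + √(α·A_out² + (1−α)·A_in²)) / (A_out − A_in)`; voxels are
  grouped into deep [0, 0.33), middle [0.33, 0.67) and superficial
  [0.67, 1] bins, after excluding the top 5 % most responsive cortical
  columns (pial-vein bias) at all depths.
* **Stripe segmentation.** Thin/thick stripe compartments from the
  z-scored color-minus-disparity differential column map (threshold ±z,
  connected components); pale stripes are the gaps flanked by one thin and
  one thick band.
* **Test–retest reliability.** Pearson correlation of two sessions'
  columnar maps, FWE-corrected by a Monte-Carlo null: the spatial ACF
  `a·exp(−r²/2b²) + (1−a)·exp(−r/c)` is fitted to session-1 GLM residuals
  and ACF-matched smooth null maps are simulated and correlated with the
  fixed session-1 map; `p = (1 + #{r_null ≥ r_obs}) / (1 + n_iter)`.
* **Informational connectivity.** Per (area × depth-bin) node: block-wise
  t-patterns → two-stage feature selection (top 20 % visually responsive,
  then 200 voxels from each tail of the differential-t distribution) →
  L2-normalised patterns → linear max-margin decoding (C = 1) under
  leave-one-run-out → signed distances to the decision boundary per
  held-out block. Connectivity of two nodes = fold-averaged Pearson
  correlation of their distance series (within-condition fluctuations).
  Feedforward = superficial(lower)↔middle(higher); feedback = deep↔deep.
  Group inference: Fisher z, one-sample t, Benjamini–Hochberg FDR over all
  pathways × contrasts.

The synthetic generator (`v2lamina.synthetic`) builds 2D cortical sheets
(V1, V2, V3ab, V4) with curvature-aware equi-volume depth samples,
interdigitated stripe maps perpendicular to the V1–V2 border, 24-s block
designs, depth-dependent gain with pial-vein bias, block-level shared
response variability between chosen region–layer pairs (the ground truth
for connectivity), and spatially autocorrelated noise.

## Worked example

Simulate and analyse a small four-subject cohort (4 runs per experiment,
24×16 columns per area) and look at the compartment profile and the
planted feedback pathway:

```python
from v2lamina import pipeline as pipe
from v2lamina.synthetic import PatchConfig

cfg = pipe.CohortConfig(
    n_subjects=4,
    runs_per_subject=(4, 4, 4, 4),
    patch=PatchConfig(area_grids={a: (24, 16) for a in ("V1", "V2", "V3ab", "V4")}),
    analysis=pipe.AnalysisConfig(n_tail=30),
    seed=7,
)
result = pipe.run_cohort(cfg)

print(result.compartment_si.groupby(["contrast", "compartment"])["si"].mean().round(3))
g = result.group_connectivity
row = g[(g.contrast == "texture") & (g.direction == "feedback") & (g.higher == "V4")]
print(row[["contrast", "lower", "higher", "direction", "mean_r", "t", "q"]].to_string(index=False))
```

which prints (~30 s):

```
contrast   compartment
color      pale           0.121
           thick         -0.003
           thin           0.420
disparity  pale           0.006
           thick          0.299
           thin          -0.110
texture    pale           0.363
           thick          0.370
           thin           0.360
Name: si, dtype: float64
contrast lower higher direction   mean_r         t        q
 texture    V2     V4  feedback 0.881999 15.634901 0.010235
```

Reading it: the estimated thin stripes carry the color selectivity
(SI 0.42 vs −0.00 in thick), the thick stripes carry disparity (0.30 vs
−0.11), and texture selectivity is flat across compartments (0.36 / 0.37 /
0.36) — while the planted deep-layer V4→V2 coupling for texture is
recovered as a strong, FDR-significant feedback connection (mean r = 0.88,
t(3) = 15.6, q = 0.01).

There is also a console script: `v2lamina validate`, `v2lamina simulate
--out DIR`, and `v2lamina all --out DIR [--stage ...]` for a full
config-driven run (YAML config via `--config`, see `v2lamina.config`).

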