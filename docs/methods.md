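# Methods

## The two-culture grazing estimator

The package estimates grazing from paired cultures: a prey monoculture
giving the intrinsic growth rate `k` and a grazed culture giving the
apparent rate `g`. Assuming exponential prey dynamics within a sampling
interval and clearance proportional to predator concentration,

    dB/dt = (k − F·C(t))·B,

the per-interval clearance is `F = (k − g)/P` and ingestion is
`I = B_avg·F`, with `B_avg` the logarithmic mean of the prey endpoint
concentrations and `P` the logarithmic mean of the predator endpoints.

Why the logarithmic mean matters: for any exponentially changing quantity
`X(t) = X₀e^{rt}`, the time average over `[t₀, t₁]` equals exactly
`(X₁ − X₀)/(ln X₁ − ln X₀)`. Using it for `P` therefore makes the
clearance estimator *exact* (to machine precision) on noiseless data even
when the predator grows exponentially within the interval — the
interval-length bias that an arithmetic-mean `P` would introduce never
arises. The test suite asserts this exactness and, separately, the weaker
10 %-accuracy property on a grid with `μ_c·Δt ≤ 0.5`.

Two growth-rate estimators are provided and used deliberately in
different places:

* **endpoint** `μ = (ln Nₜ − ln N₀)/t` — used per interval inside the
  grazing table, because clearance is defined from interval endpoints;
* **regression** `μ = e^slope − 1` with `slope` the OLS slope of
  ln concentration on time — used for whole-series summaries. The
  exponentiation is only dimensionally coherent when the slope is on the
  natural-log scale per day, which is how it is computed here.

`k` defaults to the strain-matched control's endpoint rate over the *same*
interval, keeping `k` and `g` commensurate; a whole-series (`global_k`)
option exists for users who prefer a single reference rate.

### Decline-window selection

Grazing signals are only interpretable while the prey actually declines
and the grazer actually grows. The detector scans all contiguous runs of
≥ 3 sampling points (configurable) in which prey counts strictly decrease
and the ln-linear fit has R² ≥ 0.90 (configurable), returning the longest
such run with ties broken toward the earlier window. There is no
field-standard numeric criterion for "linear decrease"; 0.90 was chosen
once as a conventional goodness-of-fit floor and is exposed as a
parameter. When depletion accelerates strongly, log-curvature can split
the decline so that only its early or late part passes the R² screen —
the detected window is then a conservative subset of the decline phase.
In `decline_window` mode, intervals outside the window or without
predator increase are emitted but flagged `outside_decline_window` and
excluded from summary means.

### Handling of degenerate counts

Zero counts make log-based estimators undefined. They are never
pseudo-counted (a +1 would bias rates precisely where the signal is
strongest, near depletion); instead the affected interval is emitted with
NaN rates and the `zero_count_interval` flag, and whole-series
regressions simply drop zero points. Negative clearance estimates
(apparent grazed growth above the control's) are reported unclamped with
a `negative_clearance` flag and *kept* in summary means by default —
censoring them would bias mean clearance upward, which the noisy-recovery
test demonstrates directly.

## Biovolume morphometry

Cell volume uses the prolate-ellipsoid formula with **full** length and
width, `V = 4/3·π·L·W²`. Note this is 8× the textbook semi-axis form
`4/3·π·(L/2)(W/2)²`; the full-dimension convention is retained verbatim
because it is the computation the downstream per-cell volumes and t-test
refer to, and consistency matters more than the constant for a
between-strain comparison. Mean strain volume is the arithmetic mean of
per-cell volumes, not the volume at mean dimensions (those differ by
Jensen's inequality for variable cells). The between-strain test is the
pooled-variance Student t-test — the only two-sample variant whose
degrees of freedom are `n₁ + n₂ − 2`, e.g. 38 for two groups of 20 cells.
Cells measured with length < width are accepted with a warning since
orientation can be ambiguous near sphericity.

## Permutation inference

The treatment analysis deliberately replaces mixed-effects modelling with
a two-stage permutation test: per-flask ln-slope as the summary
statistic, difference of group means as the test statistic, relabeling of
flasks as the null. This tests the same contrast (does grazing alter the
prey trajectory?) without REML machinery, random-effects structure
choices, or degrees-of-freedom approximations — at the cost of not
modelling within-flask correlation (absorbed by the per-flask reduction)
and of reduced power for unbalanced designs. P-values use the add-one
convention `p = (1 + #{|T*| ≥ |T|})/(1 + n_perm)`, exactly valid under
the null and never zero; designs with ≤ ~2·10⁵ distinct relabelings are
fully enumerated. Pairwise rate comparisons are Holm-adjusted (step-down,
exact under permutation) rather than Tukey-adjusted, which would assume
normal theory.

## Co-occurrence screening

Read counts of the prey taxon (large size fraction, 10–100 μm) and grazer
taxon (small fraction, 0.2–10 μm) are classified per (lake, date) sample
with strict thresholds — prey "high" above 20,000 reads, grazer "low"
below 5,000 — and tallied into four quadrants. The two fractions are
sequenced as separate libraries, so raw read numbers are not
cross-sample proportional; the summary is therefore descriptive only and
no association test is computed. A taxon absent from a sample counts as
0 reads. The complementary thresholds (prey low, grazer high) are applied
symmetrically and are configurable.

## The synthetic-data generator

The generator emulates the experimental design: three prey strains
(HL3E12, SH2A6, SF1A8) crossed with a grazer-free control and a grazed
treatment, initial concentrations 1000 prey mL⁻¹ and 200 ciliates mL⁻¹,
sampled every second day for 20 days. The predator is *exogenous*
exponential, `C(t) = C₀e^{μ_c t}` — not coupled to prey consumption —
because small prostomatid ciliates can sustain growth on bacteria or by
cannibalism, so a yield-coupled model would assert more than the
estimator assumes. The prey follows the clearance ODE above, integrated
in closed form:

    ln B(t) = ln B₀ + k·t − F·C₀·(e^{μ_c t} − 1)/μ_c     (→ F·C₀·t as μ_c → 0).

Scenario defaults, chosen once from the observed experiment:

| scenario | k (d⁻¹) | F (mL pred⁻¹ d⁻¹) | μ_c (d⁻¹) | rationale |
|---|---|---|---|---|
| strong_grazer | 0.074 | 1.0×10⁻⁴ | ln(100)/20 ≈ 0.230 | ~100-fold grazer rise over 20 d; prey depleted below 10 % of start |
| weak_grazer | 0.074 | 2.0×10⁻⁵ | ln(1.14) ≈ 0.131 | slow grazer (multiplicative rate 0.14 d⁻¹); grazed prey stays within 50–100 % of control |
| null | 0.074 | 0 | ln(1.14) | grazed flasks identical in distribution to controls |

0.074 d⁻¹ is the observed mean monoculture growth rate of *G. semen*.
Replicate counts per strain × treatment are not documented for the
original experiment; the fixture default of 3 is an assumption, chosen so
that the permutation test has 18 experimental units and fine-grained
Monte-Carlo p-values (with 1 replicate only 20 relabelings exist and no
α = 0.05 test is possible).

Observation noise models Utermöhl counting error: multiplicative
lognormal with σ = 0.1 by default (a plausible counting CV for 1-mL
Lugol-fixed aliquots), or Poisson statistics for a stated counted volume,
under which depleted cultures can genuinely hit 0 counts. What the
generator does **not** emulate: between-replicate biological variance
beyond counting noise, prey-dependent grazer yield, lag phases,
nutrient limitation in controls, or cell-size dynamics. Passing recovery
tests therefore demonstrate correctness of the estimators under the
model's own assumptions — not robustness to model misspecification in
real cultures.

## Numerical choices

* Logarithmic mean switches to its continuous limit (`B₀`) below a 10⁻⁹
  relative endpoint difference.
* Rate CSVs print 12 significant digits so write/read round-trips agree
  within 10⁻⁹ relative.
* Permutation enumeration uses a 10⁻¹² relative tolerance when comparing
  statistic magnitudes, so exact ties (e.g. identical groups) count as
  extreme and give p = 1.
* All stochastic entry points take explicit integer seeds; per-flask and
  per-pair seeds are derived through `numpy.random.SeedSequence`, making
  every output bit-reproducible. There is no wall-clock seeding.
* Validation problem sizes (112-point ODE grid, 20 noisy replicates,
  1000 calibration repetitions with 199 permutations each) were chosen as
  the smallest runs at which the measured quantities stabilize well inside
  their tolerance bands.

## Known limitations

* The clearance formulation is linear in predator concentration; no
  functional-response (Holling) saturation is modelled or fitted.
* Ingestion rates share units with neither prey growth rates nor each
  other's denominators when compared across predators of different size;
  comparisons of `I` with `k` are numeric conveniences, not dimensional
  statements.
* The permutation treatment test ignores the time-series structure beyond
  the per-flask slope; subtle non-log-linear treatment effects are
  invisible to it.
* The co-occurrence summary is descriptive; it cannot support inference
  about interaction strength.
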