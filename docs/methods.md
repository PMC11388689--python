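# Methods

This note documents the models, conventions and numerical choices behind
vfnorm, in the order the pipeline runs them.

## Test-point geometry (`patterns`)

Coordinates are integer degrees in a canonical right-eye frame (x > 0 nasal,
y > 0 superior). The 24-2 grid is the lattice of odd multiples of 3° with
|x| + |y| ≤ 30 and |y| ≤ 21, minus the two temporal 27° points — the standard
54-point chart with rows 4/6/8/9/9/8/6/4 whose two extra points sit at nasal
27°. The two points at temporal 15°, y = ±3° overlie the physiologic blind
spot; they are flagged, simulated, and excluded from every statistic
(52 analyzed points). The 10-2 grid is the odd-integer lattice with
x² + y² ≤ 89: 17 points per quadrant, 68 total, all within 9° of fixation and
all analyzed. The exact vendor 10-2 layout is not published; the radial rule
is a documented stand-in, and any layout can be substituted through the JSON
pattern format (`pattern_from_json`) without touching downstream code.

Left-eye (OS) grids are the mirror image of the canonical grid, enumerated in
the same spatial order in the left eye's own field coordinates. Mirroring a
record onto the canonical frame is a pure within-row index reversal and hence
an involution; it preserves the value multiset and all eccentricities. Tests
verify that rebuilding a model from a fully eye-relabelled, re-indexed cohort
reproduces every limit bit-for-bit.

## Synthetic cohort (`cohort`)

The generator defines the study conditions; its defaults are fixed by the
reference design and are not tuned per run.

**Demographics.** 356 included subjects with fixed age-bin counts
59/51/56/52/62/53/23 over bins 22–29, 30–39, …, 70–79, ≥80. Ages are integer
and uniform within bins; the open-ended top bin is sampled uniform on
[80, 89] (a bounded, documented choice; the design does not state the
within-bin distribution). This mixture has mean 51.9 y and SD 18.7 y, matching
the reference cohort (52.3, 18.5). Sex (44/56%), race and ethnicity are drawn
from the reference proportions; clinical eligibility fields are drawn inside
the eligible ranges. Twenty additional enrolled-but-excluded profiles carry
the tabulated exclusion reasons (6 ocular condition, 3 refractive error, 4
committee, 5 incomplete, 1 imaging intolerance, 1 elevated IOP); the
refraction and IOP profiles carry field values consistent with their reason.
Fifteen included subjects are flagged as capable only of monocular testing;
they are tested one eye at a time and contribute identically.

**Threshold model.** The noiseless threshold at point p for age a is
`B_p − β_p (a − A_ref)` with A_ref = 52.3 y (the cohort mean age, so B_p is
the cohort-mean surface). Simulated values add a subject-level general-height
offset g_i ~ N(0, σ_g²) shared across points, eyes and patterns (scaled by
the pattern's σ_g), plus independent pointwise noise σ_p·ε, and are clipped
to the instrument range [0, 40] dB.

**Skewed noise.** ε = [(1−γ)Z − γ(G−1)] / √((1−γ)² + γ²), Z standard normal,
G unit exponential. This is zero-mean, unit-variance, with third central
moment −2γ³/(…)^{3/2} < 0 for γ > 0: sensitivity losses get the heavier
tail, as perimetric normals show. Defaults γ = 0.5 (24-2) and 0.3 (10-2) —
asymmetry more pronounced in the larger field.

**Calibration.** All maps are fixed deterministically at import:

* Base maps are affine in eccentricity (−0.20 dB/° for 24-2, −0.15 for 10-2)
  with the analyzed-point mean pinned exactly to 29.1 / 32.4 dB.
* Decline maps β_p are a smooth field `(ecc/ecc_max)^q + 0.1·[superior]`
  standardized over analyzed points to mean 0.06 (24-2) / 0.05 (10-2) dB/yr
  and across-point SD 0.01 exactly. For 24-2 the shape exponent q is solved
  by a scalar root-find so that the maximum decline is exactly 2.5/30 dB/yr
  (2.5 dB over 30 years). The printed "(0.01)" on the mean slopes is treated
  as an across-point SD, not a standard error; this choice only shapes the
  default truth maps. The superior-hemifield increment reflects the larger
  aging rates away from fixation and in the superior field; for the 10-2 it
  makes inferior slopes slightly lower.
* Pointwise noise SDs are affine in eccentricity, σ_p = σ0 + σ1·ecc
  (σ1 = 0.05 /° for 24-2, 0.03 for 10-2), never decreasing with
  eccentricity. Given σ_g (0.60 / 0.33 dB), σ0 is solved once from the
  analytic between-subject variance of mean sensitivity,
  Var(MS) = (β̄·SD_age)² + σ_g² + mean(σ_p²)/N, so that cohort SDs of MS come
  out at 1.3 (24-2) and 1.0 (10-2) dB. Solved values give realistic per-point
  SDs of ≈1.3–2.5 dB (24-2) and ≈1.0–1.2 dB (10-2).
* Foveal thresholds use their own base (34.1 / 34.0 dB), the pattern's mean
  decline, the shared g_i, and a noise SD solved in closed form from the
  target total SD (4.3 / 4.7 dB). Clipping at the 40 dB ceiling trims the
  upper tail slightly (observed totals ≈3.9–4.3 dB); the mean stays within
  the calibration tolerance.

**Reliability and duration.** Catch-trial rates are scaled-Beta draws kept
strictly below the 25% gate (means 6/2/2%); with probability
`reliability_fail_prob` (default 0 — the reference study recorded no
reliability failures or retests) one index is pushed above the gate, which
exercises the retest path. Durations are normal: 3.18 (0.38) min for 24-2,
3.58 (0.43) for 10-2, clipped positive.

Each included subject receives practice and study tests of both patterns and
both eyes (8 records), pattern order shuffled per phase. Identical seed and
config reproduce the serialized cohort byte-for-byte.

**What the generator does not emulate** — the thresholding staircase and its
test-retest variability structure, stimulus timing, blind-spot catch-trial
mechanics, fatigue and learning effects, media opacities, or diseased fields.
Passing tests therefore validate the *pipeline arithmetic and its statistical
calibration*, not device behavior on real patients.

## Screening and exclusions (`qc`)

Boundary semantics are inclusive of every printed bound: age ≥ 22, logMAR
≤ 0.3 (20/40), IOP ≤ 21 mmHg both eyes, |SE| ≤ 6 D, |cylinder| ≤ 2.5 D;
reliability fails only when an index strictly exceeds 25%, so 0.25 passes.
Missing eligibility fields raise rather than pass. Retesting re-acquires both
eyes together (binocular acquisition) up to 3 attempts. One study eye per
subject is chosen by a fair coin (deterministic for monocular-only subjects)
and the same selection is shared by both patterns' analyses. Exclusion
tallies conserve counts by construction.

## Reference database (`normative`)

Pointwise OLS of threshold on age is computed for all analyzed points
simultaneously via the closed-form single-predictor normal equations
(cross-checked against statsmodels in tests); at least 3 subjects are
required. Residuals are pooled across ages — spread is modeled as
age-independent because nothing in the design suggests otherwise; a
per-decade alternative was considered and rejected as data-hungry at n = 356.
The per-point residual quantile table is stored at
0.5/1/2/5/50/95/98/99/99.5%; the lower four are the total-deviation
significance limits (upper tail stored but unused by default, following the
depressed-sensitivity convention). Residual variances s²_p get a floor of
0.01 dB² so index weights stay finite on degenerate (noise-free) input.

Quantiles use the Hazen plotting position (i − 0.5)/n with linear
interpolation, clamped beyond the extreme positions — symmetric and standard
for reference intervals; the rule is a parameter (`quantile_rule`) and other
numpy rules can be selected for comparison.

The second pass scores every cohort subject against the fitted surfaces
(two-pass construction) and tabulates: per-point pattern-deviation limits,
MD limits (lower tail), PSD limits (upper tail), and foveal-deviation limits
from the foveal threshold's own regression. The age-corrected
50th-percentile surface is the regression prediction, not per-age empirical
medians — regression is the only fitting the design describes, and at n=356
per-age medians would be unstable. Predictions outside ages [22, 90] warn
but still answer.

## Indices (`indices`)

GH is the k-th highest TD with k = ⌈0.15 N⌉ (8 of 52 for 24-2, 11 of 68 for
10-2) — the 85th-percentile-rank convention; k is configurable. MD and PSD
use the variance-weighted definitions given in the README. These are the
standard SAP conventions; the device's own unpublished choices may differ,
and the plain-text report footer says so. Probability classification is
inclusive at limits and returns the most extreme crossed level. Blind-spot
points never enter any index; the foveal threshold never enters MD/PSD.

## Sample-size simulation (`samplesize`)

The reference set is replicated 3× (263 → 789 values — fidelity to the
stated procedure; replication does not change the empirical distribution),
then n_sim datasets of size n are drawn with replacement. Per dataset, each
percentile gets the distribution-free binomial order-statistic CI: ranks
l = F⁻¹(α/2), u = F⁻¹(1−α/2)+1 of Binomial(n, level/100), clamped to [1, n],
giving guaranteed ≥95% coverage for continuous data (verified by Monte
Carlo). Adjacent percentile pairs (0.5 vs 1, 1 vs 2, 2 vs 5) are the default
overlap comparison — the binding one for ordered levels; an all-pairs mode
and a bootstrap-percentile CI are selectable.

A structural caveat, derived and tested rather than assumed: the CI ranks
depend only on (n, level, conf). At n = 356 and 95% confidence the 0.5% and
1% rank intervals both begin at the sample minimum, so adjacent extreme-
percentile CIs share order statistics and overlap *for any data*; the
per-sample non-overlap fraction is identically zero there and first becomes
attainable near n ≈ 7000 (reaching 1.0 by a few tens of thousands, as the
example shows). The fraction is non-decreasing in n, so the criterion is
safe but very conservative at reference-database scale. For a discriminating
answer at hundreds of subjects the result also reports across-simulation
CIs — the 2.5–97.5% span of each percentile's estimates over the simulated
datasets — and whether those separate.

## Problem sizes used in tests

Tests run on the full 356-subject design where the quantity under test is a
calibration target (cohort summaries over 10 seeds, slope recovery, the
flag-rate check with a 600-subject build cohort), and on reduced cohorts
(42 subjects, single pattern, no practice tests) for structural and
round-trip properties where size is irrelevant. Simulation counts (e.g. 200
resampling datasets per grid point, 2000 coverage replicates) were chosen so
binomial noise is small against the asserted tolerances.

## Known limitations

* The 10-2 layout is a radial stand-in (swappable via JSON).
* GH/MD/PSD weighting conventions are field standards, not device equations.
* Homoscedastic-in-age residual pooling; real aging may widen spread.
* The generator's noise is independent across points given the general
  height; real fields show local spatial correlation, so multi-point cluster
  criteria would look optimistic here.
* Thresholds are continuous dB; instruments round to integers, which would
  add ties to the quantile tables.
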