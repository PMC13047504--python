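# Methods

## Signal model

A voxel is two well-mixed, non-exchanging water pools with volume fractions
`f1 + f2 = 1`, apparent diffusion coefficients `ADC_i` (mm²/s) and
transverse relaxation rates `R2_i` (1/s):

```
S(TE, b) = S0 [ f1 exp(-R2_1 TE - ADC_1 b) + f2 exp(-R2_2 TE - ADC_2 b) ].
```

Internally TE is carried in milliseconds and converted to seconds inside
exponents; b stays in s/mm².  This makes the fitted R2 come out in 1/s and
both coupling slopes in mm²/s² (ADC per second of TE; (1/s) per (s/mm²) of
b), with `R2_b=0` converted to 1/ms only at report time.

The model is a *forward* model only: it generates phantom signals and
supplies the analytic polarity rule (`classify_coupling`); it is never
fitted to data.  Mono-exponential fits of its output define the *apparent*
ADC(TE) and R2(b), whose slope signs equal
`-sign((ADC_1 - ADC_2)(R2_1 - R2_2))` — a property the test suite verifies
exhaustively on random tissues.

Assumptions: no inter-compartment exchange, Gaussian diffusion per pool
(no IVIM/kurtosis), isotropic tissue (trace-weighting is simulated as a
single trace-weighted signal), and magnitude detection.

## Fitting

* **Mono-exponential NLLS.** `A exp(-k x)` by bounded trust-region least
  squares (`scipy.optimize.least_squares`, TRF, xtol=ftol=gtol=1e-15),
  initialized at the closed-form log-linear OLS solution.  Bounds:
  ADC ∈ [0, 0.01] mm²/s, R2 ∈ [0, 100] 1/s, A ≥ 0.  With exactly two
  points the exact log-ratio solution is returned; a flat series returns
  rate 0 exactly.  Noiseless mono-exponential input is recovered to better
  than 1e-9 relative (the log-linear start is already exact there).
* **Maps and ROIs.** Voxels with any non-positive sample or a
  non-converged fit are flagged and excluded from ROI means (no
  imputation).  ROI series are arithmetic means of valid voxels.
* **Coupling slopes.** Unweighted OLS of the three-point ROI series; the
  iron surrogate `R2_b=0` is the *measured* ROI-mean R2 of the b = 0
  series, not a regression intercept.
* **SNR.** `mean(signal ROI) / sigma_g`, with `sigma_g` recovered from a
  pure-noise background via the Rayleigh relation
  `SD(|N + iN|) = sigma_g sqrt(2 - pi/2)`; evaluated on the most attenuated
  image (max TE, max b).  A zero-variance background yields `inf` with a
  warning.  Applied to a NEX-averaged image the estimator returns the
  effective (averaged) noise level, which is what the protocol SNR refers
  to.

## Synthetic cohort

The generator emulates the study conditions: n = 57, ages 10–73 (uniform
by default; a per-decade sampler with counts 8/15/11/12/10/1 is available),
24 male, the factorial protocol TE {53, 71, 89} ms × b {0, 500, 1000}
s/mm² with NEX table {3,3,3 / 2,4,8 / 4,8,16} (indexed te-major), and a
worst-case SNR target of 63.8.  Geometry defaults to a 64×64×5 matrix
(3×3×4 mm voxels over a 192 mm FOV); the full-size 128×128×20 matrix is a
config switch.  Regions are bilateral ellipsoidal nearest-N voxel sets, so
label counts are exact: caudate 170, putamen 80, globus pallidus 40,
substantia nigra 20 voxels — deliberately the size scale of single-slice
manual ROIs, which (with the protocol noise level) contributes a realistic
measurement-noise floor to the per-subject metrics.

**Aging trajectories.**  Cell-body R2 rises linearly:
`R2_cb(age) = baseline + iron_rate * age`; axonal R2 is constant except
where `axon_r2_rate` is set.  The coupling sign flips at
`(R2_ax0 - baseline) / (iron_rate - axon_r2_rate)`.  Default table
(values in 1/s and 1/s/yr):

| region            | R2_ax0 | R2_cb baseline | iron_rate | axon rate | crossover |
|-------------------|-------:|---------------:|----------:|----------:|----------:|
| caudate           | 19.92  |  8.42          | 0.14      | 0.14      | never     |
| putamen           | 22.15  |  9.65          | 0.25      | 0         | ~50 y     |
| globus pallidus   | 25.02  | 18.81          | 0.27      | 0         | ~23 y     |
| substantia nigra  | 20.99  | 18.99          | 0.20      | 0         | ~10 y     |

All regions share f1 = 0.6, ADC_cb = 1.0e-3, ADC_ax = 0.6e-3 mm²/s.  These
are *calibration choices*, not measured tissue values: per-region axonal R2
and baselines were solved numerically so the simulated cohort-mean
`R2_b=0` at the mean age lands near published group means for these nuclei
(0.0169 / 0.0208 / 0.0276 / 0.0241 1/ms), and crossover ages were placed
so the putamen inverts in late middle age, the globus pallidus in early
adulthood, and the substantia nigra before adolescence (it is iron-rich
from childhood), while the caudate never inverts.  The caudate's drift is
equal in both pools — compartment-nonspecific aging — so its total R2
rises with age while its coupling stays age-flat, reproducing the
dissociation seen in vivo.  A fixed R2_ax of 22 1/s for every region
cannot reproduce the globus pallidus mean (the apparent rate of a mixture
is bracketed by its pool rates), which is why R2_ax is region-specific.

**Between-subject variability.**  Truncated-Gaussian jitter (±2 SD) on
R2_cb (1.8–3.0 1/s by region, scaled to the published per-region R2_b=0
spreads), R2_ax (0.3–1.0), relative ADC (10%) and f1 (0.05).  Truncation
keeps compartment parameters physiological; unbounded tails produced
outlier subjects that destabilized Pearson correlations.  The caudate's
jitter is deliberately cell-body-heavy (2.4 vs 0.3): shared cell-body
variance is what makes its k–R2_b=0 correlation negative even without an
age effect.  With this, the caudate's simulated R2_b=0 spread exceeds the
published one (~2.5×) — an accepted compromise.

**Noise.**  Each stored sample is the mean of NEX independent magnitudes
`|S + n1 + i n2|`, `n_i ~ N(0, sigma_g)`.  `sigma_g` is set in closed form
from the SNR target: `sigma_g = sqrt(16) * S_ref / 63.8`, where `S_ref` is
the putamen mean-age noiseless signal at (TE 89, b 1000) and 16 is that
cell's NEX.  Fast ROI mode draws the ROI mean as the average of
`n_voxels` independent voxel realizations per grid cell — statistically
identical to building the volume and averaging, at a fraction of the cost.
Rician bias is negligible at these SNRs (sigma²/2S ≈ 0.2% at the worst
grid point).

**Seeding.**  A master seed spawns one `SeedSequence` child per subject
plus one cohort-level stream (ages, sex assignment), so runs are exactly
reproducible and subjects are independent.  Default master seed: 42.

## Statistics

Per region and metric: OLS `metric = b0 + b1 age + b2 sex` (sex 0 = female,
1 = male; age uncentered for interpretability of b1); a quadratic check
adds centered-age² and its p-values are BH-corrected across the 8
region×metric tests before the keep/drop decision (α = 0.05).  All Pearson
correlation p-values of a run (20: each metric vs age and vs R2_b=0, plus
R2_b=0 vs age, per region) form a single BH family.  Raw Pearson r is
reported; the sex-adjusted linear model is reported alongside rather than
partialled into the correlation.  Complete-case analysis; dropped-row
counts are logged.  BH is implemented directly from the step-up definition
`q_(i) = min_{j≥i} p_(j) m / j` (statsmodels is used as an independent
cross-check in the tests; OLS inference itself is statsmodels).

Degenerate situations are handled explicitly: zero-residual fits are
flagged (`ModelFit.degenerate`) since their t-tests are meaningless, and
cohorts too small for the covariate models still complete with NaN entries
in the model tables.

## What the phantom does and does not show

Passing tests demonstrate that the estimation stack is unbiased and
correctly signed on two-pool tissue, that the noise model matches its
closed-form moments, and that the designed aging physiology produces the
expected population pattern: negative k–age correlations with q < 0.01 in
the three high-iron nuclei, an age-flat caudate (q > 0.05), positive
R2_b=0–age correlations everywhere (q < 0.001), negative k–R2_b=0
correlations in all four regions, no sex effect, no surviving quadratic
term.  They do *not* validate performance on real brains: the phantom has
no motion, no partial-volume mixing at ROI borders, no physiological or
registration noise, and no anatomy beyond ellipsoids, so simulated cohort
correlations (|r| ≈ 0.6–0.9) are stronger than typical in vivo values, and
the caudate's metrics come out exactly age-flat rather than weakly
declining.  The cohort-structure checks are threshold-based for this
reason, and run at one fixed master seed; a handful of alternative seeds
can fail individual sub-checks by ordinary sampling variation at n = 57.

## Problem sizes

Defaults are desk-scale by design: 64×64×5 phantom geometry, ROI-only fast
mode for cohort runs (seconds for n = 57), 200-draw sign-law and
Monte-Carlo recovery sweeps, 10⁶-draw noise-moment checks.  Full-size
volume simulation (128×128×20) and per-voxel map fitting are available
through the same interfaces when finer spatial detail is wanted.
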