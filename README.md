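# drcoupling

Diffusion–relaxation coupling analysis for multi-TE, multi-b magnitude MRI,
with a synthetic aging basal-ganglia phantom cohort for end-to-end testing.

## The problem

In heterogeneous brain tissue — the basal ganglia in particular — a voxel
mixes water pools with different diffusion and relaxation properties:
neuronal cell bodies (large, water-rich: high ADC, low R2) and axonal
tracts (dense, myelinated: low ADC, high R2). When images are acquired on a
factorial (TE, b) grid, the mono-exponential ADC fitted at each echo time
*depends on TE*, and the mono-exponential R2 fitted at each b-value
*depends on b*: longer TEs suppress the high-R2 pool, higher b suppresses
the high-ADC pool, so the surviving pool dominates the apparent rate.  This
is **diffusion–relaxation coupling**, and its polarity carries
compartment-specific microstructural information.

For a two-pool voxel

```
S(TE, b) = S0 [ f1 e^{-R2_1 TE - ADC_1 b} + f2 e^{-R2_2 TE - ADC_2 b} ],   f1 + f2 = 1,
```

the coupling polarity is set by the sign of
`(ADC_1 - ADC_2) (R2_1 - R2_2)`: a **negative** product gives *positive*
coupling (ADC rises with TE, R2 rises with b); a **positive** product gives
*negative* coupling.  The measured metrics are the OLS slopes of the
ROI-mean series,

* `k_ADC/TE` — slope of ADC (mm²/s) against TE (s), in mm²/s²,
* `k_R2/b`  — slope of R2 (1/s) against b (s/mm²), in mm²/s²,

plus `R2_b=0` (the ROI-mean R2 of the non-diffusion-weighted series,
reported in 1/ms), a surrogate for iron-related tissue properties.  Because
aging deposits iron preferentially in cell bodies — raising their R2
through the axonal value while ADC ordering is preserved — the coupling
inverts from positive (young) to negative (old) in iron-rich nuclei, and
the coupling metrics correlate negatively with both age and `R2_b=0`.

The package provides:

* `model` — the two-pool forward signal and the analytic coupling-sign rule;
* `fitting` — bounded mono-exponential NLLS ADC/R2 mapping (voxel-wise and
  ROI), coupling slopes, background-Rayleigh SNR estimation;
* `synth` — a digital basal-ganglia phantom cohort: four bilateral regions
  with age-linear cell-body R2 trajectories, between-subject biological
  jitter, and NEX-averaged Rician noise on the printed protocol
  (TE {53, 71, 89} ms × b {0, 500, 1000} s/mm²);
* `stats` — linear models with a sex covariate, a quadratic-age check,
  Pearson correlations, Benjamini–Hochberg FDR;
* `pipeline` / `cli` — end-to-end orchestration, NIfTI/CSV/JSON I/O,
  figures, manifests.

## Worked example

```python
from drcoupling import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(out_dir="demo_run"))  # 57 subjects, seed 42
print((summary.out_dir / "report.txt").read_text())
```

The default run simulates the full 57-subject cohort (ages 10–73, 24 male)
in fast ROI mode, fits every metric and writes tables, figures and
`report.txt`, which begins:

```
worst-case SNR (max TE, max b): 63.9

Per-region mean R2_b=0 (1/ms):
  caudate              0.0169 +- 0.0034 (n=57)
  globus_pallidus      0.0272 +- 0.0027 (n=57)
  putamen              0.0205 +- 0.0042 (n=57)
  substantia_nigra     0.0238 +- 0.0019 (n=57)

Correlations (Pearson r, BH-FDR q):
  caudate              k_adc_te  vs age    r=+0.01 q=0.95
  ...
  putamen              k_adc_te  vs age    r=-0.88 q=8.8e-19
  putamen              r2_b0     vs age    r=+0.90 q=3.8e-20
```

Reading: the measured SNR at the most attenuated grid point matches the
protocol target (63.8); the regional `R2_b=0` hierarchy is globus pallidus
> substantia nigra > putamen > caudate; the coupling metrics fall steeply
with age in the three high-iron nuclei but are age-flat in the caudate —
whose `R2_b=0` nevertheless rises with age, because its simulated R2 drift
is compartment-nonspecific and therefore leaves the coupling untouched.

The same run is available from the shell:

```sh
drcoupling all --seed 42 --out demo_run            # fast ROI mode
drcoupling simulate --volumes --out vol_run        # write NIfTI volumes
drcoupling fit --input vol_run --out refit_run     # re-analyze from disk
drcoupling stats --metrics demo_run/cohort_metrics.csv --out stats_only
```

## Limitations

The phantom is a calibration instrument, not a brain atlas: regions are
ellipsoidal blobs, partial-volume mixing, motion and physiological noise
are absent, and the generator's baselines/rates are chosen so cohort means
land near published group values for these nuclei.  Cohort correlations are
correspondingly stronger than in vivo ones.  See `docs/methods.md` for the
model, calibration, and numerical details.
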