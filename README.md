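# scanmap

Analyses of interdigitated motor-cortex networks on synthetic
cortical-strip data.

Precision functional MRI has shown that the classic foot-to-face motor
homunculus on the precentral gyrus is interrupted by three
*inter-effector* regions — strongly interconnected with each other and
with the cingulo-opercular control network (CON), thinner, later in
infra-slow signal timing, weakly movement-selective, and more active
during action planning than execution — alternating with the
effector-specific foot, hand and mouth zones, and that each effector
zone is organized concentrically (distal movements at the center,
proximal ones in surrounding rings). `scanmap` provides tested,
reusable implementations of the statistics behind those claims,
together with a deterministic synthetic-data generator that reproduces
the data *structure* of such a study (interdigitated region covariance,
injected pairwise lags, haemodynamic responses with one- or two-peak
spatial profiles along a 1-D dorsal→ventral cortical axis,
region-structured structural maps) so that every estimator can be
validated against known ground truth without any imaging downloads.

It is aimed at methods developers and reviewers who want to probe how
these analyses behave — their calibration, power and failure modes —
under controlled conditions.

## What is implemented

- **Connectivity** (`scanmap.connectivity`) — Fisher-z functional
  connectivity `Z(r) = atanh(r)` of vertex time series and of
  region-mean time courses, a seed sweep down the cortical axis,
  percentile thresholding (ties kept), the conservative contrast
  `z_target − max[z_foot, z_hand, z_mouth]`, the per-network smallest
  inter-effector-minus-effector difference, and paired t-tests with
  Benjamini–Hochberg FDR.
- **Lag structure** (`scanmap.lags`) — lagged cross-covariance
  functions of infra-slow (<0.1 Hz) signals, sub-frame extremum
  refinement by three-point parabolic interpolation, antisymmetric
  time-delay (TD) matrices (`td[i,j] > 0` ⇔ signal *i* is later), and
  per-region mean-lag projections.
- **Task GLM** (`scanmap.glm`) — block (15.4 s) and zero-duration event
  designs convolved with a double-gamma HRF, vectorized OLS with
  per-vertex t→Z maps, second-level one-sample t across runs, the
  paired planning-vs-execution contrast, and Gaussian map smoothing
  (σ = 2.55 axis units by default).
- **Somatotopy** (`scanmap.somatotopy`) — nearest-point projection onto
  the axis, winner-take-all preferred-movement maps (top-1% display
  masking), movement selectivity (best minus second-best activation),
  region coactivation profiles, LOWESS profile curves, and the
  one- vs two-peak Gaussian model comparison

      Activation = a₁·exp(−((x−b₁)/c₁)²) [+ a₂·exp(−((x−b₂)/c₂)²)]
      F = ((SSE₁−SSE₂)/(df₁−df₂)) / (SSE₂/df₂)

  with amplitudes constrained non-negative and df = n_points − n_params.
- **Synthetic data** (`scanmap.synthetic`) — the generator described
  above, with ground truth (`SyntheticTruth`) for every injected
  quantity.
- **Pipeline + CLI** (`scanmap.pipeline`, `scanmap` console script) —
  simulate → connectivity → lags → GLM → somatotopy → structural →
  report over a multi-subject synthetic cohort, with validated JSON/YAML
  configs, deterministic seeding and TSV/JSON outputs.

## Worked example

```python
import numpy as np
import scanmap as sm

strip = sm.generate_strip()                      # 120-vertex axis + CON/S1/background
truth = sm.default_truth(strip, seed=42)
runs = [sm.generate_rest_run(strip, truth, n_frames=600, tr=1.1, seed=s)
        for s in (1, 2, 3, 4)]

labels = np.where(np.isin(strip.region_labels, sm.synthetic.INTER_REGIONS),
                  "inter_effector", strip.region_labels)
print(sm.region_mean_connectivity(runs, labels, "inter_effector", "CON"))
print(sm.region_mean_connectivity(runs, strip, "foot", "CON"))
```

prints `1.884` and `0.328`: the inter-effector regions are far more
strongly connected to CON (Fisher z ≈ 1.9) than the foot region is
(z ≈ 0.33), as injected (they share a latent signal with CON).

```python
from scanmap.lags import td_matrix, mean_lag_projection, motor_lag_groups
td = td_matrix(runs, strip, elements=list(sm.synthetic.MOTOR_AXIS_ORDER) + ["CON"])
print(mean_lag_projection(td, groups=motor_lag_groups()).round(3))
```

```
CON               0.445
inter_effector    0.023
foot              0.298
hand             -0.546
mouth            -0.268
```

Positive values lag (arrive later). For this single simulated subject
the mean effector lag (−0.17 s) < inter-effector (0.02 s) ≤ CON
(0.45 s), matching the injected 0 / +0.4 / +0.8 s timing; cohort
averages in the pipeline recover the ordering much more tightly.

```python
x = np.arange(60.0)
y = sm.synthetic.gaussian_profile(x, ((3.0, 18.0, 5.0), (3.0, 46.0, 5.0)))
y += np.random.default_rng(0).standard_normal(60)
prof = sm.AxisProfile(positions=np.arange(60), activation=y,
                      fit_mask=np.ones(60, bool))
fit1, fit2 = sm.fit_peak_models(prof)
comp = sm.compare_models_f(fit1, fit2)
```

gives `one-peak SSE=93.6  two-peak SSE=34.2  F(3,54)=31.3  p=7.47e-12`
with fitted centers `b1=19.0, b2=45.9` — the two-peak model is decisively
preferred and both injected centers (18, 46) are recovered to within one
axis unit.

The full cohort pipeline, from the shell:

```sh
scanmap report --seed 1 --out scratch/report       # 20 subjects, ~1 min
scanmap simulate --seed 1 --out scratch/subj0      # one subject's raw data
```

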