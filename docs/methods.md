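# Methods

This note documents the models implemented in `scanmap`, the synthetic
data they are validated on, the numerical choices made where the design
was open, and what the validation studies do and do not show.

## The synthetic cortical strip

All analyses operate on a 1-D dorsal→ventral cortical axis standing in
for the 2-D precentral gyrus sheet; geodesic distance is the absolute
difference of integer axis positions. This is adequate because every
implemented statistic is defined either along the dorsal–ventral axis
or on region sets. The default strip has six 20-vertex motor regions in
interdigitated order — foot, superior inter-effector, hand, middle
inter-effector, mouth, inferior inter-effector — giving a 120-vertex
axis, plus 20-vertex off-axis CON, adjacent-S1 and background
territories at a lateral offset (so Euclidean nearest-axis projection
is well defined).

### Resting-state model

Each region's signal is
`w_g · g(t − τ_r) + w_n · s_k(r)(t − τ_r)`, plus independent white
vertex noise. The latents `g` (global, shared by all regions) and
`s_k` (network-specific) are Gaussian white noise brick-wall low-pass
filtered below 0.1 Hz in the frequency domain (the infra-slow band) and
standardized; the FFT filter is used for exact reproducibility.
Region lags `τ_r` are injected by a frequency-domain phase ramp
(band-limited interpolation), which supports fractional (sub-TR) shifts
exactly — necessary for testing sub-frame parabolic interpolation. The
shift is circular; with run lengths of hundreds of frames and lags
≤ 1.5 s the wrap-around is negligible.

Defaults (the simulated study conditions): global weight 0.6, network
weight 0.8, vertex noise sd 1.0, TR 1.1 s, 4 rest runs × 600 frames per
subject (≈ 44 min — a realistic precision-imaging budget; single short
runs leave infra-slow lag estimates dominated by the ~60 effective
samples below 0.1 Hz). Latent assignment: one latent per effector; the
three inter-effector regions *and CON share one latent* (the injected
coupling); S1 shares the hand latent; background has its own. Injected
lags: effectors 0 s, inter-effector +0.4 s, CON +0.8 s (positive =
later), reproducing the effector → inter-effector → CON temporal
ordering.

What this emulates: interdigitated region covariance, a global
component, infra-slow spectra, fixed pairwise lags. What it does not:
1/f and physiological noise, motion artefacts, spatial autocorrelation
of noise, hemodynamic variability across regions, volumetric geometry.
Passing tests therefore certify the estimators against this generative
model, not against the full complexity of real BOLD data.

### Task model

Block designs follow the movement-battery timing (15.4 s blocks — a
2.2 s cue plus 12 paced movements at 1.1 s — two blocks per movement
and three rest blocks per run). The per-vertex response amplitude of a
movement is its Gaussian spatial profile `a·exp(−((x−b)/c)²)` (one or
two peaks) evaluated at the vertex's axis position, optionally plus a
region-wise beta (used to co-activate CON with axial movements and to
drive the planning/execution event task). Time courses are amplitude ×
(boxcar ∘ HRF) plus white noise (sd 2.0 by default).

The HRF is a double-gamma kernel: gamma density with mode 6 s minus
1/6 × gamma density with mode 16 s, truncated to a 32 s support and
normalized to unit peak. Regressors are sampled directly on the frame
grid (no supersampling); with the default TR the 15.4 s block covers
exactly 7 frames before convolution.

Default battery truth: single peaks (a = 3, c = 6) at the foot, hand
and mouth centers for toes / hand / tongue; two-peak profiles
(a ≈ 1.2–1.6) over pairs of inter-effector centers for abdominal,
eyelid and swallowing, giving interdigitated winner-take-all bands,
deliberately weak inter-effector selectivity, and inter-effector/CON
coactivation structure. The event task activates inter-effector
regions more during planning (β 1.2 vs 0.6) and effector regions more
during execution (β 0.3 vs 1.2).

Structural maps are per-region normal draws: thickness 2.3 mm
(inter-effector) vs 2.7 mm (effectors), sd 0.15; FA 0.45 vs 0.40;
myelin between the foot and hand values, and the returned myelin map
is normalized by its mean over the motor strip (so that mean is
exactly 1). Between-subject variability is added as a per-region mean
jitter (sd 0.05).

All generators derive their RNG streams from a root seed with fixed
offsets; outputs are byte-identical under a fixed seed, and the
zero-noise limit equals the analytic signal model exactly (asserted in
tests).

## Connectivity

Correlations are clipped to ±(1 − 1e−7) before `atanh`, so z is always
finite. Vertexwise matrices are symmetric with the diagonal and
zero-variance vertices masked. Region connectivity is the correlation
of region-*mean* time courses (mean-then-correlate), which differs from
the mean of pairwise vertex correlations; the former is implemented
because it is the natural region statistic here. Multi-run inputs are
standardized per run and concatenated. Seed maps exclude the seed's own
vertex from thresholding statistics; percentile thresholding keeps ties
at the threshold, making survivor sets nested across increasing
thresholds. Group seed maps average Fisher z across subjects rather
than recomputing from averaged matrices.

The conservative contrast is `z_target − max over competitors`; the
per-network summary statistic is the smallest difference between
inter-effector and any effector connectivity, averaged across subjects,
with a two-tailed one-sample t against zero per network and BH-FDR
across the declared family. The FDR family is always exactly the set
of comparisons passed in. Zero-variance difference vectors are handled
explicitly: all-zero → t = 0, p = 1; constant nonzero → flagged
degenerate and excluded from FDR.

## Lag structure

The lagged cross-covariance of standardized series is
`CCF(k) = (1/n) Σ x(t)·y(t+k)` over the valid overlap, for
k ∈ [−L, +L] (default L = 8 frames). The extremum is taken as the CCF
*maximum* (in-scope signals are positively correlated) and refined by
three-point parabolic interpolation,
`τ = (k₀ + ½(c₋−c₊)/(c₋−2c₀+c₊))·TR`. Pairs are invalid when the peak
|CCF| < 0.3 (noise guard), the peak sits at the window edge, or the
curvature vanishes; thresholds are configurable.

Sign convention, fixed package-wide: `td[i,j] > 0` ⇔ signal *i* occurs
later than signal *j*; since the CCF above peaks at `τ_j − τ_i`, the TD
entry is the negated extremum location. One triangle is estimated and
mirrored, so antisymmetry is exact by construction. Session-level TD
matrices are averaged over the sessions in which each pair is valid.
The mean-lag projection is the row mean over valid off-diagonal
entries, optionally averaged within region groups; with a full validity
mask the group means conserve the element-weighted grand mean
(asserted as a property test).

The 1/n normalization tapers the CCF toward large |k|, biasing
extremum locations slightly toward zero; on noiseless band-limited
shifts up to 1.5·TR the bias is below 0.05·TR (asserted), and under
the validation conditions (800 frames, SNR 2) the median absolute
error is ≈ 0.06 s for shifts of 0.5–1.5 s.

## Task GLM

Ordinary least squares per vertex (vectorized normal equations),
t = β/SE with df = frames − columns, and a sign-preserving probability
transform of t to Z, clamped at |Z| = 8.2 to avoid infinities. No
autocorrelation prewhitening is applied — a deliberate divergence from
FEAT-style first-level models, harmless here because the synthetic GLM
noise is white (under the null the vertexwise Z maps are standard
normal to Monte-Carlo precision, which is asserted). Rank-deficient
designs are rejected with the collinear columns named. The second
level is a one-sample t of run betas (df = runs − 1); zero-variance
nonzero betas are flagged degenerate and excluded. The
planning-vs-execution map is the paired t of matched run betas,
positive where planning exceeds execution.

Note that t→Z conversion is nonlinear: with few runs it compresses
large effects, flattening the tops of strong activation profiles. Peak
*locations* are preserved, but a flattened single peak can be decomposed
by the two-peak model into two nearby Gaussians; the pipeline therefore
measures center recovery as the mode of the fitted curve.

Map smoothing is 1-D Gaussian convolution along the axis ordering with
an edge-including ("symmetric") reflected boundary; the smoothing
matrix is then doubly stochastic, so constants and the map mean are
preserved exactly. Default σ = 2.55 axis units (vertex spacing ≈ 1 mm
in the synthetic geometry).

## Somatotopy

Vertices are assigned the ordered index of their Euclidean-nearest
axis point (ties to the lower index); activation profiles are
unweighted per-position means of vertex Z (positions differ in vertex
count in general; weighting was considered and not adopted — documented
choice). Fit masks are axis-fraction exclusions per movement class:
lower/upper-extremity movements exclude the ventral third, face
movements the dorsal third, trunk movements nothing.

Peak fitting is constrained nonlinear least squares (trust-region
reflective, analytic Jacobian) under a ≥ 0, b within the masked range,
c ∈ [0.5, range]. The width floor of 0.5 axis units prevents
delta-spike fits. Multi-start is deterministic: center candidates at
the masked-range deciles, width starts {2, 5, 10}, all starts ranked by
initial SSE with the best few polished; the two-peak starts include
all decile center pairs, a residual-peak seed, and the one-peak
optimum with a vanishing second amplitude — the last guarantees
SSE₂ ≤ SSE₁ exactly (nested models). Two-peak parameters are reported
in canonical order b₁ ≤ b₂, and fits whose centers collapse to within
one axis unit are flagged. df = n_fitted_points − n_params (3 or 6).

The model comparison is the extra-sum-of-squares F-test,
`F = ((SSE₁−SSE₂)/(df₁−df₂)) / (SSE₂/df₂)`, with the upper-tail p from
the F(df₁−df₂, df₂) distribution; the two-peak model is preferred at
p < α (default 0.05).

**Known caveat — the F-test is anti-conservative under the one-peak
null.** The second peak's location and width are nuisance parameters
that exist only under the alternative (Davies' problem): the optimizer
is free to place the second Gaussian on the largest noise excursion, so
the SSE reduction stochastically dominates the χ²₃-like drop the F
reference distribution assumes. Under the validation conditions (60
positions, one-peak truth, noise sd = 0.5·a₁) the empirical size at
α = 0.05 is ≈ 0.28 and p-values are strongly non-uniform. This is a
property of the procedure itself, not of the implementation — the same
machinery detects genuine well-separated two-peak profiles with power
≈ 1 at p < 0.001 and recovers their centers with median error
≈ 0.5 axis units. Conclusions based on this test are therefore safe
only when F is far beyond its nominal critical value; a calibrated
alternative would require a resampling or scan-corrected reference
distribution, which is out of scope here.

Winner-take-all resolves exact ties to the earliest condition
(flagged) and supports a top-percent display mask (default top 1%).
Selectivity is best minus second-best activation. Coactivation
profiles are region-mean activations per movement, correlated between
regions (constant profiles are masked); conditions can be excluded
(e.g. motion-distorted ones). LOWESS smoothing uses locally weighted
linear regression with tricube weights and one robustness iteration;
the span must give at least 3 points per local fit.

## Pipeline

The pipeline simulates a cohort (default 20 subjects), runs every
stage per subject, and assembles group tables: the per-network
min-difference table with FDR flags, per-subject lag projections with
paired tests, winner-take-all band checks (per subject and on the
cohort-averaged Z maps), peak-fit tables with F-tests, selectivity and
planning-contrast summaries, structural comparisons, and recovery
metrics against the injected truth. Everything is deterministic given
the config seed (per-subject and per-run streams are derived with
fixed offsets); the report records a config hash and content checksum.
Thresholds default to the study's printed analysis choices (α = 0.05,
edge threshold Z(r) > 0.2, seed-map percentiles 80–97, top-1% display).
An `inter_con_coupling=False` switch provides the negative control in
which CON gets its own latent: the CON min-difference then collapses
to ≈ 0 and loses significance.

Problem sizes throughout (vertices per region, runs per subject,
replication counts in the validation studies) were chosen as the
smallest configurations at which the targeted effects are comfortably
identified; the full validation suite and the 20-subject cohort run in
a few minutes on one CPU.

## Limitations

- The 1-D axis ignores 2-D geodesic geometry, the medial wall, and
  cortical folding; the upper-extremity medial-wall exclusion
  degenerates to the ventral-third exclusion.
- White synthetic noise means the GLM calibration results do not speak
  to autocorrelated real BOLD noise (where prewhitening would be
  required).
- The lag validity threshold (peak |CCF| ≥ 0.3) and window (±8 frames)
  are package defaults, not values inherited from any reference
  implementation.
- The F-test caveat above: its nominal size is not attained under a
  free-location null and results near the critical value should not be
  trusted.
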