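# Methods

This note documents the models, conventions and numerical choices behind
`limbcoord`, and what the synthetic cohorts do and do not establish.

## Phase estimation

Interlimb coordination is quantified per stride of a reference limb
(left hindlimb by default). The horizontal foot trajectory is oriented
so the slow stance drift rises toward a peak: peaks mark swing onsets,
troughs stance onsets, and a stride is the half-open interval between
consecutive swing onsets (the last partial stride is truncated at the
final swing onset). Peak detection uses `scipy.signal.find_peaks` with a
minimum inter-peak distance of half the autocorrelation-estimated stride
period and a prominence of 20% of the trajectory range — scale-free
defaults that are exposed in configuration because no canonical values
exist.

For a stride of duration `d` frames, the phase of another limb is the
argmax lag of the mean-subtracted cross-correlation between the two
trajectories over integer delays in [−d/2, d/2], converted to
2π·lag/d and wrapped to [−π, π). Positive phase means the other limb
lags the reference. Ties are broken toward the smaller |lag| and there
is no sub-frame interpolation, so the quantization error is one lag,
2π/d (at 400 fps and a 0.25 s stride, 0.02π rad). Mean subtraction is
the default and can be disabled. Phases are estimated independently
from the two tracked landmarks of each foot; if the two estimates
differ by more than 0.1π (circular distance) the stride is dropped.
Strides with a zero-variance window are dropped with a flag rather than
given an arbitrary phase.

Two known estimator properties on synthetic data: (i) when fore and
hind limbs have different duty factors the differing waveform shapes
bias every phase estimate by a constant (≈ half the duty-factor
difference in cycle units, ~0.05π at 0.55 vs 0.60); (ii) when phase
varies stride to stride, the correlation window (which extends d/2 into
the neighboring strides) shrinks each estimate toward its neighbors.
Both effects are constant within a trial and cancel in covariate
effects and phase *shifts*, which is what the downstream analyses use;
absolute phase values carry that offset.

## Posture, speed and inclusion rules

The snout–hump angle is 180° − |elevation| of the hump→snout vector in
surface-parallel coordinates — an obtuse angle approaching 180° when
the vector is parallel to the surface, invariant to rotating the scene
together with the surface and to uniform scaling. Elevations above and
below surface-parallel are folded by absolute value; coincident points
are a degenerate-geometry error. Trials are included when ≥ 90% of
snout and hump frames and ≥ 80% of reference-limb frames have tracking
likelihood ≥ 0.95; sub-threshold frames of all bodyparts are linearly
interpolated and flagged. Locomotion is belt speed strictly above
1 cm/s; contiguous runs define bouts, and all stride analysis is
per-bout. When no belt channel exists, speed falls back to the median
rearward foot velocity during stance.

## Load analysis

Standstill is detected as the longest run of 1 s rolling windows whose
total-load coefficient of variation is below 5% (both parameters
configurable; only the ≥ 5 s duration rule is canonical). Weight
fractions are mean channel loads over that window normalized to sum to
one. The dimensionless CoS is fore-minus-hind (AP) and right-minus-left
(ML) fraction differences; the cm-valued CoS is the load-weighted mean
foot position and is only reported when foot coordinates are available.
On a slope θ only cos(θ)·weight is detectable by vertical load cells;
the offload fraction is 1 − detected/(cos θ·weight). Weight-adjusted
head height is (h − 24.5)/(1.25·W) with W in grams, equal to 1 at the
maximum comfortable height 24.5 + 1.25·W (mm). Exponential decay fits
y = A − B·e^(−kx) use `scipy.optimize.curve_fit` initialized with A =
max(y), B = A − y_first, k = 1/mean(x); constant data yields a flagged,
k-less fit, and near-linear data can converge to a degenerate large-A /
tiny-k solution that is an equally good least-squares description —
consumers should inspect `rmse` and the parameter scale.

## Circular statistics

The von Mises KDE is the mean of VM(φᵢ, κ = 10) kernels on a 200-point
grid, renormalized so the periodic Riemann integral is exactly 1.
Mixtures of 1–4 von Mises components are fitted by EM (concentration
via the Best–Fisher A₁ inverse with Newton refinement, κ capped at 500
with a flag on near-degenerate clusters, 5 random-responsibility
restarts, seeded). Model selection is by BIC with ties toward fewer
components; BIC replaces a posterior-predictive criterion because the
fit is maximum-likelihood, not Bayesian. A fit counts as unimodal when
(1) it has one component, (2) the dominant component holds ≥ 80% of the
weight, or (3) two components jointly hold ≥ 80% and their means differ
by < 0.2π.

Circular-linear regression is a maximum-likelihood von Mises model with
mean direction μ(x) = μ₀ + 2·atan(βᵀ(x − x̄)) + γ_group, sum-to-zero
group (mouse) offsets and a shared concentration, optimized by L-BFGS-B
with an analytic gradient. Covariates are centered (absorbing the
link's inflection point) and screened by variance inflation factor
(> 5 dropped). Intervals are percentile bootstrap over 500 (default)
case resamples drawn mice-first then strides-within-mouse; a covariate
is significant when its interval excludes zero. This replaces a
Bayesian projected-normal sampler deliberately: the scientific contract
— the direction and significance of each covariate's effect on a
unimodal circular response — is preserved at a fraction of the
machinery, and the interval-excludes-zero rule plays the role of a
posterior interval excluding zero. Per-group random *slopes* are
approximated by a two-stage fit-per-group mode rather than estimated
jointly. The intercept-only model reduces exactly to the circular mean.

## Support patterns and lateralization

The 16 raw contact states are grouped into eight categories (four-limb,
three-limb, diagonal pair, homologous fore, homologous hind,
homolateral pair, single limb, no contact); the raw fractions are also
emitted since the grouping is a package convention. PCA is on centered,
non-standardized fractions (they share units), signs fixed by making
each PC's largest-magnitude loading positive, components retained to
90% cumulative variance. PC projections are regressed on covariates
with a random-intercept linear mixed model (OLS fallback for a single
group).

The side classifier is a linear SVC (C = 1; kernel and C configurable —
no canonical values exist) on (sin φ, cos φ) features, 75/25 split with
the training portion balanced per (mouse, label) by subsampling, ROC
from decision scores, and an add-one permutation p-value
(1 + #{perm ≥ obs})/(1 + n_perm) that cannot reach zero.

## CoS mapping

Linear CoS-vs-covariate maps are fitted with sum-to-zero mouse
contrasts (≥ 4 covariate levels required; extrapolation outside the
fitted range is an error). Composing μ(x) with x(CoS) yields the phase
shift relative to the most fore-loaded end of a CoS window, with a
bootstrap band propagated from the regression's β draws. The
equivalence experiment generates one cohort in which the mean phase is,
by construction, linear in CoS at 0.25π per 0.4 cm posterior shift for
*both* manipulation pathways: the forelimb-load law is placed in its
near-linear regime and the link slopes are derived from the chain
dμ/dCoS = 2β / (dCoS/dcovariate). Recovery of that law by the full
pipeline, with overlapping bands across trial types, is the package's
end-to-end check.

## Synthetic cohorts: what they are and are not

The generator's defaults are the study conditions: 400 fps video, head
heights 32–57 mm, slopes −40°…40°, weights 20–28 g, 0.25 s stride
period, duty factors 0.55 (fore) / 0.60 (hind), phase concentration
κ = 8 (circular SD ≈ 0.12π, matching observed per-condition spread),
per-mouse direction offsets with SD 0.1 rad, 0.5 mm tracking noise,
2% likelihood-dropout frames at 0.5. The homolateral link defaults to
μ₀ = 0.8π, β_angle = −0.03 rad/deg about an inflection at 160°, and
β_slope = −0.006 rad/deg, producing the alternation-to-quarter-phase
sweep over the tested ranges; hindlimb phase is von Mises around π.
Load trials realize a forelimb fraction A − B·e^(−k·h) (A = 0.33,
B = −1.5, k = 0.05/mm: ~63% forelimb load at the lowest head height
and a ~1.1 cm posterior CoS shift over 25 mm), a 0.0035/deg linear
slope shift, head-post offload growing 0.006/mm above the minimum
height, 1% channel noise, and a 6 s standstill after a 2 s movement
lead-in sampled at 100 Hz (a desk-scale rate; the standstill analysis
is rate-invariant).

Limb trajectories are stance/swing sawtooths smoothed by a short moving
average, with two landmarks per foot sharing the true phase plus a
small jitter. One cohort seed expands to per-trial generators through
`numpy.random.SeedSequence(seed, spawn_key=(stream, mouse, trial))`, so
generation is bit-reproducible and order-independent. The generator
does not emulate: video appearance, vertical body dynamics (foot y is
cosmetic), head-free kinematics, falls, stimulation-latency dynamics,
within-trial covariate drift, or autocorrelated phase sequences.
Passing tests therefore establish estimator correctness and calibration
under the assumed generative structure, not robustness to real-world
tracking artifacts.

## Problem sizes

Cohort sizes were chosen as the smallest at which the checked effects
are statistically unambiguous: recovery experiments use 12 mice × 500
strides (phase-level draws), the end-to-end composition 6 mice × ~40
strides per condition through the full trajectory pipeline with
200-resample bootstraps, and null calibrations 20 seeded replicates.
The analysis drivers default to a 4-mouse demonstration cohort.
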