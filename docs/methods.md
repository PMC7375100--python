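# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the underlying
definitions left room.

## Subject-level pipeline

The fixed order of the subject-level branch is

```
drop initial volumes → nuisance regression → band-pass (lFCD branch only)
→ local statistic → whole-brain-mean normalization → smoothing
```

**Volume dropping.** The first `n_drop` frames (default 5) are removed from
the data and the motion trace consistently, to avoid T1 saturation at the
start of an EPI run.

**Motion QC.** Framewise displacement follows the Power convention:
FD_t = Σ|Δtranslation| + Σ|r·Δrotation| with head radius r = 50 mm. A
subject is excluded when their mean FD is at least 2 sample SDs above the
group mean, with group statistics computed over all subjects before any
exclusion. When the group SD is exactly zero nobody is excluded — the rule
targets outliers and a zero-variance group has none (a literal "≥ mean + 0"
reading would absurdly exclude everyone).

**Nuisance sets.** The lFCD branch regresses out 16 signals: 6 rigid-body
motion parameters, their backward-difference derivatives (leading row zero),
a linear trend, the in-brain global mean, and the WM and CSF means. The
FOCA branch omits the global mean (15 signals). An intercept is always
included implicitly; constant-zero columns (e.g. a motionless trace) are
dropped with a warning, and rank-deficient designs drop collinear columns
greedily. Only a linear trend is removed; whether a quadratic trend should
also be removed is left to the caller (it is not part of these recipes).
The global mean is computed within the brain mask.

**Band-pass.** A zero-phase hard mask in the DFT domain retaining
0.01–0.08 Hz, with DC always removed. This is idempotent and exactly
analyzable (a bin-aligned tone in the passband is preserved to machine
precision); a Butterworth filter would satisfy the same contract. Only the
lFCD branch is filtered; the FOCA branch is not (exposed as a config
override), because FOCA's spatial-stability term draws information from
frame-to-frame structure that heavy low-pass filtering inflates trivially.

**tSNR gate.** Voxels enter the lFCD computation only if temporal mean/SD
≥ 50. tSNR is evaluated on the detrended-but-not-residualized series:
nuisance residualization destroys the signal mean that SNR needs. The
threshold comparison is inclusive, and a constant positive voxel (SD = 0)
counts as infinite SNR.

**Smoothing.** Gaussian with σ = FWHM/(2√(2 ln 2)) per axis, converted from
mm to voxels via the affine. Convolution is mask-renormalized — the masked
image and the mask are smoothed separately and divided — so a constant
in-mask image stays constant and values near the brain edge are not dimmed.

## lFCD

Growth is seed-correlation based: a candidate adjacent (26-connectivity by
default; 6 and 18 available) to any current cluster member joins when its
correlation **with the seed** strictly exceeds r = 0.6. This is the
seed-growing reading of functional connectivity density mapping; a
neighbor-chaining variant (link any adjacent pair whose mutual correlation
exceeds the threshold; each voxel scores its connected-component size) is
available as `mode="chain_corr"`. The raw value counts the seed itself, so
the minimum on an included voxel is 1; excluded voxels get 0. Growth is
unbounded — no maximum radius is imposed. Supplementary-style sensitivity
thresholds 0.5 and 0.7 are plain parameter changes, and raw values are
provably non-increasing in the threshold (tested voxelwise).

Implementation: voxel time courses are demeaned and ℓ2-normalized once, so
any correlation is a dot product. A vectorized pre-pass computes all 26
neighbor-pair correlations; only seeds with at least one supra-threshold
neighbor enter the Python BFS, which keeps the common case (isolated seed,
value 1) out of the slow path. The tests compare against a literal
flood-fill oracle that computes every seed-to-voxel correlation explicitly.

## FOCA

The exact weighting of FOCA's two ingredients is not fixed by its verbal
definition, so this package documents its reconstruction explicitly:

- T = mean pairwise Pearson correlation among the time courses of the
  in-mask members of the voxel's 3×3×3 neighborhood (cube clipped, not
  zero-padded, at edges; the center voxel is a member);
- S = mean Pearson correlation between the neighborhood's value pattern at
  frame t and at t+1, averaged over frame pairs; a frame pair in which a
  pattern has zero variance (up to a relative 100·ε tolerance) is skipped
  and logged;
- FOCA_raw = (T + S)/2. Geometric-mean and product combinations are
  available behind a flag. Negative raw values are kept.

Voxels with fewer than 2 in-mask neighbors get 0. Vectorization rests on
the identity Σ_{i<j} zᵢ·zⱼ = (‖Σ zᵢ‖² − N)/2 for unit-norm, zero-mean time
courses, which reduces T to cubic box sums (and S to box sums of x, x² and
x·x_next); the tests verify agreement with a literal double-loop oracle to
1e-10.

## Normalization

Each subject map is divided by its mean over included voxels, after which
the in-mask mean is 1 by construction. Degenerate voxels (zero temporal
variance, SNR-gated, or too few neighbors) hold value 0 and are excluded
from the normalizing mean. A nonpositive mean raises an error rather than
producing a silently sign-flipped map.

## Group statistics

OLS at every voxel of the stacked, normalized, smoothed maps on
[1, age_c, age_c², sex, meanFD, ICV] (age model) or
[1, behavior, sex, meanFD, ICV] (behavior model), where age_c = age − mean
age. Centering before squaring tames the age/age² collinearity; it changes
β1's interpretation (slope at the mean age) but provably not β2's t-value,
which the tests verify numerically. The uncentered variant is a flag.
Sex is coded female = 0, male = 1 (affects only β3's sign). Rows missing
the behavior score are dropped per model. t = β̂/SE with df = n − p and
two-tailed p-values, since effects of both signs are of interest. Voxels
with zero residual variance (relative tolerance 1e-12) are flagged and
excluded from inference.

FDR is Benjamini–Hochberg at q = 0.05 over in-mask voxels, applied
separately per coefficient and per statistic (not pooled across maps).
Cluster reporting labels the surviving mask split by t sign, 26-connectivity
by default (18 available, the SPM convention), and discards components with
≤ 30 voxels — the extent rule is strict, a 30-voxel component fails. Each
cluster row reports size, signed peak t, and the peak's grid and world
coordinates. Anatomical (atlas) labeling of clusters is out of scope.

## Synthetic cohorts

The generator emulates the structure of a lifespan resting-state cohort at
desk scale: default 100 subjects, ages uniform over 18–88 (a stand-in for
per-decade quota sampling, which matches it in expectation), sex Bernoulli
at 0.5, a 20×20×20 grid of 3 mm voxels with an inscribed-ellipsoid brain
mask (~3100 voxels), 200 frames at TR 1.97 s, and a constant baseline of
1000 so the default tSNR is baseline/noise_sd = 100, comfortably above the
gate of 50.

**Planted effects.** Region voxels follow the mixing model
x_v = baseline + noise_sd·(w·s_R + √(1−w²)·ε_v) with unit-variance white
sources, so the expected pairwise correlation is exactly w². Setting
w = √c plants coherence c(age) = base + slope·(age − ā) + quad·(age − ā)²,
with ā the mean age; specs whose coherence leaves [0.01, 0.99] anywhere in
the age range are rejected at construction. The default conditions plant
two 4×4×4 regions at base coherence 0.5 with slopes ∓0.004/yr. When
noise_sd = 0 the latent alone drives the region and within-region
correlations are exactly 1.

**Background realism.** Out-of-region voxels get unit-variance noise with a
small spatial point-spread (Gaussian σ = 0.35 voxels, variance restored),
plus a shared global signal (SD 3 against voxel noise SD 10, i.e. a
background inter-voxel correlation of ~0.08 before nuisance regression).
All stochastic sources are AR(1)-colored with lag-1 autocorrelation 0.3.
Both choices mirror acquired BOLD (point-spread blur, temporal
autocorrelation) and are load-bearing: with spatially and temporally white
background, the whole-brain mean of raw FOCA is ≈ 0 — slightly negative
after residualization — and dividing by it is meaningless. Because the
coloring is a single linear filter applied to every source, expected
correlations (and hence all planted coherences) are unchanged; only the
effective temporal degrees of freedom shrink, as in real data.

**Motion and phenotypes.** Motion is a reflected random walk (per-step SD
0.02 mm for translations, 0.02/50 rad for rotations, bounds ±1 mm / ±0.02
rad), giving mean FDs in a realistic 0.05–0.2 mm range; motion_sd = 0 gives
an identically zero trace. ICV is lognormal around 1.45×10⁶ mm³. The
fluid-intelligence-like score declines linearly with age
(42.4 − 0.18·age + N(0, 4.2²), chosen so the age–score correlation is
strong, r² ≈ 0.4, on the score's 12–44 scale), and the two reaction-time
scores rise with age with matching scale and noise.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: scanner artifacts (spikes, drift beyond
linear, physiological noise), anatomy and tissue contrast (the WM/CSF
"tissue masks" are stand-in blocks of background noise), motion-by-signal
interaction (motion corrupts the trace, not the images), hemodynamic
spectra beyond AR(1), and spatial normalization error. Results on real
cohorts additionally depend on registration quality and the atlas-level
anatomy of effects, neither of which exists here.

**Reproducibility.** One RNG root is split per subject by counter
(SeedSequence spawn keys), so subject i's data depends only on (seed, age,
i) — not on cohort size — and identical specs reproduce identical bytes.

## Problem sizes for the validation studies

The planted-effect recovery study uses twenty 100-subject cohorts at the
default grid and the lFCD statistic; the null-calibration study uses twenty
60-subject cohorts with no planted regions and the FOCA statistic (a
continuous-valued map whose null t-statistics are closest to their nominal
distribution; null lFCD maps are nearly constant — almost every raw value
is 1 — so their p-values are visibly discrete). Each cohort analysis runs
in tens of seconds on one CPU; the subject-level computations use float32,
which changes the statistics at the 1e-6 level, far below Monte-Carlo noise.

For the uniformity check, pooled null p-values are decimated to every 4th
voxel per axis (12 mm spacing, beyond the 8 mm smoothing kernel) before the
Kolmogorov–Smirnov test: smoothing correlates neighboring voxels, and a KS
test on tens of thousands of dependent p-values would reject for dependence
alone, not miscalibration.

## Known limitations

- The FOCA weighting (arithmetic mean of T and S) is a documented
  reconstruction; alternative weightings are exposed but not calibrated
  against an external implementation.
- Seed-correlation growth and neighbor-chaining growth disagree on data
  with long correlation chains; only the default is validated against the
  recovery study.
- The FD exclusion rule is a hard threshold; no scrubbing or censoring of
  individual high-FD frames is implemented.
- The voxelwise GLM is homoscedastic OLS; no robust or mixed-effects
  variants, and no permutation-based cluster inference.
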