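# Methods

This note documents the models, conventions and numerical choices behind
`odoresp`, what the synthetic generator does and does not emulate, and the
known limitations.

## Signal model and ΔF/F extraction

Fluorescence of each voxel is modeled as

```
F(t) = F_base × (1 + Σ_odor a(v, odor) · k_ch(t − t_onset) · d_ch(session)
                  + Σ_groups s_g · z_g(t)
                  + g_ch · m(t) + ε(t)),   clipped at 0,
```

where `k_ch` is a difference-of-exponentials response kernel with unit
peak, `d_ch` a per-session multiplicative drift, `z_g` smooth latent
fluctuations shared by coupled voxel groups, `m` the motion trace, and `ε`
i.i.d. Gaussian noise in ΔF/F units.  The kernel family
`exp(−s/τ_decay) − exp(−s/τ_rise)` (s = t − delay) was chosen because its
two time constants map directly onto the phase-delay and pulse-width
metrics the analysis recovers; its peak time
`delay + τ_r τ_d/(τ_d − τ_r) · ln(τ_d/τ_r)` and FWHM have closed/numeric
forms used for parameter-recovery checks.

ΔF/F uses a causal sliding-window baseline: for frame *i*, F₀ is the mean
of the lowest `ceil(0.3 · w)` intensities among the previous
`w = min(200, i)` frames.  Early frames use all available history
(discarding the warm-up would lose the resting-state segment); frame 0,
with no history, is defined as 0.  The implementation partitions strided
window views and is exactly equal (not approximately) to a per-frame
sort-and-mean computation; the suite asserts this at 1e−12.

A non-positive baseline raises an error — ΔF/F is undefined there — except
at frame 0, whose output is 0 by definition and whose self-baseline is
therefore not checked.

## Generator defaults and what they emulate

Defaults mirror the standard experimental design: 3 odors × 60 sessions =
180 trials, 5 s stimuli, 30 s inter-trial intervals, pseudo-random order
with each session a permutation of the odor set and no immediate repeats.
The default voxel grid is 24×24×8 with 8 box-shaped regions (4 olfactory);
tests and the acceptance script run smaller grids (8×8×4 or 6×6×2) and a
shortened resting segment (20–30 s instead of the 10-minute default) — the
resting duration only matters for resting-state connectivity, and these
sizes keep full runs in minutes on one CPU.

Channel kinetics defaults: calcium (delay 0.2 s, rise 0.3 s, decay 3 s)
and ACh (0.2/0.4/3.5 s) are fast; a serotonin-like channel (slower rise
and decay) is available via config.  Drift defaults are qualitative
presets — calcium decays across the four stages (×1.0/0.85/0.7/0.55), ACh
stays flat through the first three, serotonin drops only from stage 1 to
2 — and are config-driven, not claims about any dataset.

Each odor's default ensembles occupy 10–20% of each olfactory region's
voxels (the fraction cycles with the odor–region pairing so that region
*means* also carry odor information, as real odors recruit neuropils
unevenly) at peak ΔF/F 0.5 against noise sd 0.1.  The per-voxel noise of
denoised volumetric data is not publicly characterized; the default is an
arbitrary but plausible choice and is swept in tests.

The behavior video is constructed so that its per-frame mean absolute
difference *equals* the planted motion trace exactly (a spatially uniform
frame whose level takes steps of size m(t), reflecting at a bound), making
motion-energy extraction exactly invertible.  The generator does not
simulate optics, photon noise, denoising artifacts, or motion-correction
residuals; passing tests therefore demonstrate correctness of the analysis
chain and recoverability under the stated statistical structure, not
robustness to those acquisition-level effects.

## Response metrics

Responsiveness is the Pearson correlation of each voxel with the binary
stimulus sequence, masked at two-sided p < 0.05 (exact t reference, the
same null as `scipy.stats.pearsonr`); zero-variance voxels are masked, not
errors.  Phase delay is measured from odor onset (not from a response
threshold crossing, which is noise-sensitive); FWHM uses linear
interpolation at the half-maximum crossings.  Odor tuning is the mean
per-trial AUC for the probed odor minus the pooled other odors — pooling
(rather than a pairwise minimum) was chosen as the simpler reading —
with per-voxel two-sided Mann–Whitney U, BH-corrected across voxels.
Note that a voxel driven by a *different* odor is genuinely negatively
tuned for the probed odor; recovery tests count detections as
significant-and-positive and define false positives on never-tuned voxels.

## Connectivity and the complementation statistic

Correlations are computed over response records spliced across all trial
windows.  Region-level networks keep the full weighted matrix; voxel-level
networks keep the top 30% of correlations (ceiling count, ties broken by
node order for determinism).  Community detection runs on positive-weight
edges only (modularity with negative weights is ill-defined); Louvain is
seeded at resolution 1, and the greedy algorithm plus the adjusted Rand
index serve as a consistency check.  Degrees sum signed weights; the
community ratio restricts to positive weights — both conventions are
flagged in the API documentation.

The deflation ratio (M − M̄)/M̄ uses the off-diagonal mean (the unit
diagonal is non-informative), making the dual-channel difference matrix Δ
invariant to positive rescaling of either channel — asserted at 1e−12.
Clusters for Δ_w⁺ − Δ_b⁺ are Louvain communities of the calcium voxel
graph; matrix *display* ordering uses average-linkage hierarchical
clustering on 1 − r.  An empty positive class contributes a mean of 0.

## Decoding

All tiers share: PCA fitted on training frames, LDA fitted on the single
frame at offset 2 from odor onset (features span offsets 0–13), all frames
re-expressed in LDA space, and a linear SVM (C = 1, one-vs-rest) on the
flattened trajectories, under stratified seeded 5-fold CV.  Variance
thresholds: 0.8 (region tier), 0.998 (brain-region averages), 0.9
block-wise plus a 25-dimensional global PCA (multi-region tier; blocks are
10×10×10 voxels, accuracy maps use 4×4×2).  A linear kernel was chosen —
the alternative kernels would forbid composing the PCA and LDA matrices
back to voxel space for identification-weight maps.  Trials of one session
may fall into different folds.  Nothing from held-out trials enters any
fit; a guard test asserts the fitted transforms are byte-identical when
test trials are perturbed.

Dual-channel decoding applies the block-wise PCA per channel and
concatenates the outputs before the global PCA; at the 4×4×2 accuracy-map
tier the channels are concatenated as raw features.  A duplicated channel
scales PCA scores by √2, so "no gain" for identical channels holds within
CV noise, not bitwise.

## Manifolds

Wide-window (−2 s to +33 s) trials are projected through the transforms of
the fold that held them out.  Fold alignment uses orthogonal Procrustes
(rotation/reflection only) on class-mean trajectory matrices, with the
residual reported so misalignment is detectable; LDA scale differences
between folds are not corrected (no scaling step), which inflates
residuals but preserves each fold's geometry.  Distances are Euclidean in
LDA space.  The origin is the mean location at the first time point.
`t_fifth` and `t_random` search for downward crossings only after the
trajectory's peak (before the rise, the level is trivially below
threshold) and interpolate linearly between samples.  Stage analysis
splits sessions into four contiguous blocks; return locations are session
means over 29–30 s, reported on the first two discriminant axes.

## Motion analysis

Motion energy is the pixel-mean absolute frame difference.  Behavioral
features are the first 30 PCs of per-trial motion windows with a
deterministic sign convention (largest loading positive).  Behavior-based
decoding feeds the PCs to the SVM unscaled: PCs are centered and
variance-ordered, and standardizing them would amplify the low-variance
noise components and destroy that ordering.  Ridge variance partitioning
(λ = 1 on standardized predictors; λ = 0 is forbidden) fits the
behavior-only model on all trials; the residual is the exact complement of
the fitted values, so the two reconstruct the neural PCs identically.
Because the removal is in-sample, cross-validated classification of the
residual can dip *below* chance when the removed component carried all the
class signal — the expected signature of a fully motion-routed signal.
With 30 behavior PCs the partition needs the full 180-trial design;
at a third of that the ridge visibly absorbs odor signal by chance.
Lagged correlation uses linear interpolation for sub-frame shifts;
positive lag means neural activity delayed relative to motion.

## Scheirer–Ray–Hare test

All observations are ranked jointly with midranks; two-way ANOVA sums of
squares are computed on the ranks from factor-, and cell-level means; each
effect's H = SS_effect / MS_total is referred to chi-square with the
effect's df, where MS_total = SS_total/(N−1) computed from midranks — this
is algebraically identical to dividing the untied rank variance
N(N+1)/12 by the standard tie-correction factor, so ties are handled
without a separate correction step.  An all-tied sample returns H = 0,
p = 1.  The suite checks agreement with an independent rank-ANOVA oracle
(statsmodels OLS on ranks) to 1e−10 and an empirical type-I error of
0.045 at α = 0.05 over 2000 balanced null replicates.  The standard
battery (Mann–Whitney, Wilcoxon, KS, Kruskal–Wallis) delegates to scipy
behind a uniform record with rank-biserial effect sizes; one-sided
directions must be stated explicitly.

## Problem sizes

The default test and acceptance runs use: 180 trials on 8×8×4 grids for
chance calibration and planted-signal recovery; 20 sessions on the same
grid for the dual-channel gain replicates; 12 sessions of 8×8×4 for
coupled-cluster complementation; 16 sessions of 6×6×2 for stage-drift
recovery; 60 sessions of 6×6×2 for motion partitioning.  These sizes were
chosen so each property is measured at the trial counts that matter for it
while a complete run stays within minutes.

## Known limitations

- The generator's noise is Gaussian and white; real denoised data has
  structured residuals.
- Atlas regions are axis-aligned boxes; no irregular morphology, partial
  voluming, or registration error.
- Procrustes fold alignment ignores LDA scale differences between folds.
- The Δ_w⁺ − Δ_b⁺ statistic depends on the detected cluster structure; with
  weak clustering its sign is unstable, so only the comparative statement
  (cross- vs within-cluster coupling) is tested.
- No nonlinear embeddings, causal connectivity, modularity null models, or
  cross-animal alignment.
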