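# Methods

This note documents the statistical model behind `neuropcr`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions a user auditing results will want to know.

## The decoding model

Let xᵢ ∈ ℝᵖ be subject i's ROI feature vector: the three contrast maps
(M−F, M−S, F−S) masked to the region of interest and concatenated in that
fixed block order, voxels in ascending linear index within each block, so
p = 3·|ROI|. With sample mean x̄ and the top two principal components
P = [PC1; PC2] of the column-centered sample matrix, each subject is reduced
to a weights row

    wᵢ = (PC1·(xᵢ − x̄),  PC2·(xᵢ − x̄),  1).

Stacking sample rows into W (n−1 × 3) and the measured scores into
Y (n−1 × 2, columns BDI-II and AAI), the model map is

    M = W⁺ Y,

where ⁺ is the SVD-based Moore–Penrose pseudoinverse (singular values below
`max_dim · eps` relative to the largest are dropped). W⁺Y is the
least-squares solution of WM = Y of minimum Frobenius norm; when W has full
column rank it coincides with the normal-equations solution
(WᵀW)⁻¹WᵀY — both identities are asserted against independent oracles in the
test suite. A held-out subject's predicted scores are ŷ = wM, unclipped;
categorical diagnoses apply strict cut-offs, predicted BDI-II > 13.5 for
depression (the clinical cut of ≥14 adapted to continuous predictions) and
predicted AAI < 4 for insecure attachment.

The PC weights are computed by projecting the *centered* feature vector onto
the orthonormal components. This is the standard PCR convention; it makes
"subject at the sample mean" map to zero weights exactly and keeps w₁, w₂
free of the constant column's overlap with non-zero-mean components. The
sample mean stored in the basis is the one reused for held-out subjects;
nothing about the test subject enters the centering.

### Cross-validation

The evaluation is leave-one-out with *nested* selection: for every fold the
group Z maps, the ROI, the PC basis, and the model map are refit from the
n−1 sample subjects only. Deriving the ROI once from all subjects would leak
the held-out scores into feature selection and invalidate the error
estimate; the suite asserts, bitwise, that replacing a held-out subject's
psychometrics changes nothing in that subject's fold. A full-cohort ROI is
still emitted by the `roi`/`loo` commands — for inspection, never for
prediction.

### ROI selection

For the sample subjects, each voxel of each contrast map is regressed by OLS
on [1, BDI-II, AAI] (both regressors jointly, with intercept). Each
regressor's t statistic (n−3 df) is mapped to a standard normal Z through
matching tail probabilities, computed tail-wise so |Z| ≈ 38 is still exact.
The ROI is the union over the six (contrast, regressor) maps of voxels with
|Z| strictly above 4.265; the one-sided rule (Z > 4.265) is available via
`RoiConfig(two_sided=False)`. Two-sided is the default because negative
score–activity associations are exactly as usable by a linear regression as
positive ones. The threshold sits just inside the one-sided P < 10⁻⁵ level
(Φ̄(4.265) ≈ 9.98·10⁻⁶). The group model is plain OLS with normal-theory
t→Z — a deliberate, self-contained replacement for mixed-effects group
machinery; per-subject contrast variance maps are not used at the group
level. No cluster-extent rule is applied: the selection rule is voxelwise,
and contiguity of the resulting ROI is an empirical outcome, not a
constraint. If no voxel passes anywhere (possible on weak-signal synthetic
cohorts), the `fallback_k` = 50 strongest voxels are taken instead, with a
logged warning — this keeps every fold runnable and mirrors the ~50-voxel
ROI scale the rule is intended to produce.

Features are contrast *effect* values. Per-subject Z or variance-scaled
features would entangle ROI size with noise estimates; the effect values are
the quantity the amplitude model is linear in.

## First-level analysis

- **HRF**: double-gamma, response delay 6 s, undershoot delay 16 s, unit
  dispersions, undershoot ratio 1/6, 32-s support, peak-normalized to 1.
  These are the conventional canonical parameters; all are module constants.
- **Design**: per condition, the TR-gridded event indicator convolved with
  the HRF sampled at the TR; confound columns (e.g. motion parameters,
  white-matter signal) are appended exactly as given — centering is the
  caller's responsibility — and the intercept is last. Onsets are snapped to
  the TR grid (events in the simulator are TR-aligned by construction).
- **Smoothing**: separable Gaussian, σ(axis) = FWHM / (2√(2 ln 2)) / voxel
  size, reflect boundary, truncated at 4σ, applied frame-wise to the time
  series before fitting. Default FWHM 9 mm.
- **GLM**: voxelwise OLS; σ² = RSS/(frames − rank X). No prewhitening or
  AR noise model — exact under the simulator's white noise, an approximation
  on real data where serial correlation would make the reported contrast
  variances optimistic (the fixed-effects weights, being relative, are less
  affected). Rank-deficient designs are rejected with the collinear columns
  named (pivoted QR).
- **Fixed effects**: runs are combined by inverse-variance weighting;
  combined variance 1/Σ(1/vᵢ), which never exceeds any input variance.
  Voxels with a non-positive input variance (noiseless simulations) fall
  back to the unweighted mean with a logged warning.

## The synthetic cohort

The generator emulates the study conditions the decoder targets: 14 control
+ 14 depressed women, BDI-II uniform-integer on [0, 12] (controls) and
[11, 54] (depressed) — the two groups' observed score ranges, which overlap
at 11–12 — AAI coherence on [1, 9] negatively correlated with BDI-II
(latent-Gaussian coupling, ρ = 0.5 by default), four 12.6-minute runs at
TR 2 s (378 frames), 2×2×3 mm voxels, and a single contiguous cluster of 50
voxels (random BFS blob) in a 16×16×10 grid whose per-condition response
amplitude is linear in the subject's scores:

    amp(c; bdi, aai) = α_c + β_c·bdi + γ_c·aai.

Defaults: α = 1 for all conditions; β_M = 0.08, β_F = 0.02, β_S = 0 per
BDI-II point (depressed subjects respond more strongly to Mother-involving
contrasts); γ_M = −0.02, otherwise 0; noise sd 0.5 (i.i.d. Gaussian, white
in space and time). The slopes are free calibration parameters — no effect
sizes in physical units exist to copy — chosen from a power argument: the
group-level t for a cluster voxel of the M−S contrast across 27 subjects is
roughly β·sd(bdi)·√n / σ ≈ 0.08·15·5.2/0.5 ≈ 12, comfortably above the 4.265
cutoff, so ROI selection is exercised in its intended regime rather than at
its detection edge. Linearity of the planted model is intentional: the
decoder is linear, and the simulator tests whether the pipeline recovers a
linear score–activity relationship when one exists — it cannot tell you
whether real depression is linearly encoded.

Not emulated: serial (AR) noise, scanner drift, motion, physiological
artifacts, between-voxel noise correlation, anatomical structure, or
multi-cluster effects. Passing recovery tests therefore certifies the
*pipeline's* correctness and hygiene, not its expected accuracy on real
scans. Determinism: every draw comes from a stream keyed on
(seed, subject id hash, operation salt), so any artifact is reproducible in
isolation, and `simulate` + `loo` at a fixed seed is byte-identical
end to end.

The fast rendering path emits contrast maps directly from the amplitude
model (planted amplitude on cluster voxels, zero elsewhere, noise
everywhere); the BOLD path renders full 4-D runs — baseline 100 plus
HRF-convolved event responses on cluster voxels plus noise — and is tied to
the fast path by an end-to-end test: the first-level pipeline applied to a
noiseless BOLD render recovers the planted contrasts to well under 1%.

## Numerical conventions and edge cases

- Voxel linear index: 0-based, (x, y, z), x fastest — fixed so feature
  ordering is deterministic and fold artifacts are comparable.
- sform is preferred over qform when a NIfTI carries both.
- PCA sign: each component's largest-magnitude loading is positive; repeat
  calls are bit-identical.
- Strict inequalities at all thresholds (|Z| > 4.265, BDI > 13.5, AAI < 4):
  a value exactly at a threshold is *not* selected/diagnosed.
- Metrics with zero denominators (e.g. specificity with no controls) are
  reported as undefined (`None`/`null`), never silently 0.
- Percentages are reported at 1 dp alongside exact integer fractions
  (13/14 prints as 92.9% but is stored as [13, 14]).
- Agreement is compared to chance with an exact binomial test at p = ½; for
  the attachment labels this is reported as context, not a claim of
  significance.
- Degenerate folds (non-finite prediction, empty sample) abort with the
  held-out subject named, rather than dropping subjects silently.

## Problem sizes

Tests and the acceptance script run cohorts of 28 subjects on grids of
16×16×10 (default) or 10×10×6 voxels with 30–50-voxel clusters, and BOLD
simulations on 2-minute runs over 6×6×4 grids. These sizes keep the full
fold-wise pipeline — 28 refits of Z maps, ROI, PCA and model map — in the
seconds range while leaving every selection step in its intended operating
regime (the planted cluster is found by thresholding, not by fallback).

## Known limitations

- OLS-only noise model at both levels (no prewhitening, no mixed effects).
- No registration, slice timing, or motion estimation: inputs are assumed
  spatially aligned; motion enters only as caller-supplied confounds.
- Exactly two principal components by default (`n_components` is exposed);
  no regularization; no nonlinear decoders.
- Predictions are unbounded; a pathological fold can predict BDI-II outside
  [0, 63], which is preserved (and visible) rather than clipped.
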