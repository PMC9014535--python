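# Methods

## Eigenimage decomposition of regional perfusion

Each task stage yields a participant × region matrix of mean rCBF
(ml/100 g/min). Row-centring subtracts each participant's mean across all
regions, removing global perfusion so that components reflect *relative*
regional patterns. The stress-stage matrix is factorised with an
economy-size SVD; the number of components equals the smaller matrix
dimension (59 in the reference design of 59 participants × 120 regions; 44
at the default simulated joint sample of 26 + 18).

Conventions that the factorisation leaves open are fixed as follows:

- **Score convention.** Network activity scores are the columns of `U`,
  not `U S`. This is the only convention under which the rest-stage
  projection `U*_rest = X_rest,ctrd (S Vᵀ)⁺` returns scores commensurate
  with `U`: feeding the stress matrix back through the projection
  reproduces `U` exactly, and identical Rest and Stress inputs give
  `ΔU ≡ 0`.
- **Sign convention.** Each component is oriented so that its
  largest-|loading| region loads positively. SVD signs are otherwise
  arbitrary and would flip downstream regression signs between runs.
  Consequently the *sign* of any coefficient involving a component's
  activity is interpretable only relative to that component's eigenimage
  orientation.
- **Pseudoinverse truncation.** Singular values below
  `max(n, p) · eps · s_max` are treated as zero (the standard rcond rule);
  configurable via `StressNetworkSVD(rcond=...)`.
- **Winner-takes-all ties.** A region whose largest absolute loading is
  attained by several components is assigned to the lowest component
  index. Ties have measure zero in real data; the rule only pins down the
  degenerate case.
- **Both matrices are row-centred** before use, including the rest matrix
  prior to projection.
- **No component selection.** All `min(n, p)` components propagate to
  inference; the explained-variance profile is reported, and the
  family-wise threshold scales with the number of components evaluated.

## GC expression summary

Delta-CT is the geometric mean of housekeeping CT values minus the gene's
CT (higher = more expression). Participants enter the summary only with
non-outlier values on all eight markers. The retained table is
column-centred (per-marker mean removal, no variance scaling — delta-CT
values share a common cycle scale, and centring is the only preprocessing
the summary assumes) and decomposed by SVD; component-1 scores
(`U₁ s₁`, the projection of the centred data on the first loading vector)
are the summary. The component is oriented so its correlation with a
reference marker (CD8+ GILZ by default, the marker the summary tracks most
closely) is non-negative, making reruns deterministic. Per-marker
correlations with the summary are reported as a similarity profile.

Centring per marker rather than per participant is deliberate: the brain
module's per-participant centring removes global perfusion, which has no
analogue across eight heterogeneous delta-CT scales. Both the centring
axis and variance scaling are fixed design choices, not options.

## Quality control

Tukey fences at `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR` with linearly interpolated
quartiles (the common default of mainstream numeric stacks; the estimator
is configurable because fences depend on it). Values *strictly* beyond a
fence are excluded, so boundary values are retained. Framewise
displacement is screened once per fMRI condition; each delta-CT marker is
screened separately. Analysis sets are complete-case: fMRI analyses use
participants passing both FWD screens, gene analyses those passing all
eight marker screens, joint analyses the intersection. No imputation.

Descriptive group comparisons use the pooled-variance two-sample t-test
(df = n₁ + n₂ − 2) computed from group summary statistics and the Pearson
χ² test without continuity correction — the variants that reproduce the
published cohort-table statistics from the published summaries.

## Repeated-measures LMM

Per region, uncentred rCBF from both stages is modelled with fixed effects
stage, group and stage × group (the interaction regressor is the
elementwise product of the 0/1 stage and group codings) plus sex, age,
disease duration, task load, BDI and an intercept, and a random intercept
per subject. With exactly two observations per subject the model is fitted
exactly by transforming each subject's pair into an orthogonal
within-subject difference (variance σ²ₑ) and between-subject sum
(variance σ²ₑ(1 + 2λ), λ = σ²_b/σ²ₑ) and profiling the REML criterion over
λ — a one-dimensional bounded optimisation whose every evaluation is one
weighted least squares. The REML denominator is chosen so that in the
covariate-free case the stage t equals the paired t-test exactly;
coefficients and t-statistics agree with `statsmodels` `MixedLM`
(REML) to ~1e−6, which the test suite asserts.

Permutation inference per covariate of interest, two-sided on |t|, with
p = (b + 1)/(B + 1):

- **stage** — stage labels are flipped independently within each subject
  (a sign flip of the within-subject contrast) and the model refitted;
- **interaction** — the interaction regressor is rebuilt from flipped
  stage labels while the observed stage main effect stays in the model, so
  a true stage effect remains modelled under the interaction null (this
  keeps the test calibrated, which the suite verifies empirically);
- **group** — a between-subject regressor cannot be permuted within
  subject; a Freedman–Lane scheme permutes reduced-model residuals at the
  subject level across subjects.

When the flip space `2^n_subjects` is no larger than the requested number
of permutations, the stage/interaction tests enumerate it exhaustively and
the p-value (count/2ⁿ, identity included) is seed-independent.

## Robust regression and the permutation Wald test

Tukey bisquare M-estimation: tuning constant c = 4.685 (95% Gaussian
efficiency), scale = median(|r|)/0.6745 re-estimated each IRLS iteration,
OLS start, convergence when the largest coefficient change is below 1e−8,
cap 50 iterations. The covariance is the Huber-corrected form
`k² · [Σψ² s²/(n−p)] / ψ̄′² · (XᵀX)⁻¹` used by the mainstream robust
regression implementations; with it, the Wald statistic of a single
covariate of interest equals t² identically, matching how robust t and W
values are conventionally reported together.

The permutation null for the Wald statistic of the CI block is generated
by residualising the CI columns on the nuisance columns, permuting the
residualised regressor across observations, and refitting the full robust
model (studentized regressor permutation, asymptotically valid under
heteroscedastic errors). A Freedman–Lane variant permuting reduced-model
robust residuals is available (`permute="residuals"`); both calibrate at
nominal level in the suite's null simulations, and the regressor scheme
has the lighter null tail and hence more power. When n! does not exceed
the requested B, all permutations are enumerated. Refits across
permutations run as one batched IRLS (shared iteration loop over a
(B, n, p) design stack), which is what makes 10⁴ permutations per model
practical.

Standardized β rescales a raw coefficient by sd(predictor)/sd(outcome);
binary predictors are standardized identically. Labels: |β| < 0.2 weak,
0.2 ≤ |β| < 0.5 moderate, |β| ≥ 0.5 strong.

## Severity models

In patients only: each severity outcome is modelled on the selected
network's ΔU (or on the GC summary) with disease duration, sex, age, task
load (brain models; the gene models omit it), BDI and a constant as
nuisance. Lesion voxel counts are transformed as `ln(count + 0.001)`
before modelling; the natural log is used — the base affects only the
coefficient scale, not t or p. Each of the four outcomes is tested at an
uncorrected two-sided α = 0.05 (one a-priori hypothesis and a single CI
per model). The relative importance of the selected network is reported by
refitting the severity model once per network and ranking all networks by
|t|; a failed fit ranks last.

If several components pass the family-wise interaction threshold, each is
modelled separately and flagged; if none passes, the pipeline models the
top-Wald component for reporting, flagged as not family-wise significant.

## Synthetic cohorts

The generator emulates the study design so every stage is testable with
known ground truth. Defaults are the study's analysis conditions; they are
fixed, not tuning knobs.

- **Sample**: 26 patients, 18 controls; 120 regions; demographics drawn
  around the published group summaries (age ≈ 47 ± 12 vs 42 ± 17, BDI
  ≈ 9.8 ± 7.5 vs 2.8 ± 2.3, sex ratios ≈ 25/39 and 17/25 female).
- **Brain**: 5 orthonormal network loadings; latent score scales
  `12 · 0.6^k`, residual sd 1.0 per region, global perfusion 55 ± 6 —
  chosen so the leading stress component explains ≈ 45% of centred
  variance, the reported profile of the reference analysis. Rest scores
  are stress scores minus a per-subject stress shift
  `(0.5 + 0.5·N(0,1)) · scale_k`; the shift along the designated network
  (default: the leading one, keeping the planted component identifiable at
  n = 44) is the planted differential activity.
- **Genes**: one unit-variance latent factor loading on the eight markers
  (GILZ-heavy, FKBP4-light, so the summary's similarity profile mirrors
  the reported one); marker noise noise_sd/3, giving a first component
  that explains ≈ 75% of marker variance. In patients the factor carries
  the planted standardized interaction effect: with x̃ the standardized
  group × differential-activity regressor, factor = β·x̃ + √(1−β²)·ε, so
  the standardized coefficient the pipeline measures is ≈ β (−0.76 by
  default).
- **Severity**: lesion load and EDSS couple at +β_sev, SDMT at −β_sev
  (0.43 by default), grey-matter fraction is uncoupled; log-lesion is
  linear in the planted score so the analysis transform recovers
  linearity. EDSS is rounded to half-steps and SDMT to integers, mildly
  attenuating planted effects as real scales would.
- **Outliers**: a chosen fraction of participants receive a +10·IQR offset
  on an FWD or marker value, guaranteeing detection by the 1.5·IQR fence.

What the generator does *not* emulate: spatially structured eigenimages
(loadings are random orthonormal, not anatomically smooth), non-Gaussian
rCBF noise, missing data, or any coupling between covariates and brain or
gene signals. Passing tests therefore demonstrate the statistical
machinery under the assumed generative structure, not robustness to the
full messiness of acquired data.

## Calibration and power at desk scale

Monte-Carlo checks in the acceptance suite use these problem sizes: null
calibration of the robust interaction test on 200 null cohorts at B = 500
(α = 0.05), family-wise error over all 44 components on 30 null cohorts at
B = 1000 (the smallest B at which the corrected threshold 0.05/44 is
attainable, since min p = 1/(B+1)), and planted-effect recovery on 100
cohorts at B = 10000.

A power observation worth stating explicitly: at the design sample
(26 + 18) with a planted standardized interaction of −0.76, the permutation
null of the studentized robust Wald statistic has a substantially heavier
far tail than the asymptotic χ²₁ at this n, so clearing the family-wise
threshold 0.05/44 demands an observed statistic larger than essentially
every permuted one. The acceptance suite and `scripts/acceptance.py`
measure the consequence directly: the planted component reaches
family-wise significance in only a minority of replicates (on the order of
one in three to one in five, seed-dependent), even though the planted
effect size itself is recovered accurately. The detection-rate check in
the acceptance suite asserts majority detection and is expected to fail at
this sample size; it is retained deliberately as an honest record of
attainable power rather than weakened. Single-test calibration,
effect-size recovery (mean β̂* ≈ −0.8 at planted −0.76), severity
sign recovery (> 90%) and family-wise error control all pass at the same
scale.

## Reproducibility

All randomness flows from explicit seeds; stage-level substreams are
derived by hashing the top-level seed with the stage name, so any stage
can be reproduced in isolation. Identical config and seed give
byte-identical outputs. Outputs are TSV tables with JSON sidecars stamped
with the seed and a config hash.
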