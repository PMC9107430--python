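# Methods

## Study design emulated by the simulator

The package analyses a within-subject pharmacological challenge: each
Parkinson's-disease patient with baseline tremor is scanned and scored OFF
medication (overnight withdrawal) and again ON medication (about an hour
after a standard carbidopa/levodopa dose). Subcortico-cortical functional
connectivity is summarised per session as Fisher-z Pearson correlations
between 96 cortical parcels and two seed sets: 8 dopaminergic nuclei
(bilateral thalamus, caudate, putamen, pallidum) and 4 cholinergic
basal-forebrain regions (bilateral BF123 and BF4). Patients are phenotyped by
tremor responsiveness — the relative drop in the UPDRS III tremor sub-score
(items 20 + 21) from OFF to ON — and median-split into dopamine-responsive
(at or above the median; ties go up by the "above or equal" rule) and
dopamine-resistant groups.

The synthetic cohort reproduces this design:

* **Time series.** Each subject-session is a T × 108 zero-mean Gaussian
  series (default T = 200 volumes; a typical 6–7 minute scan at TR = 2 s;
  scan length is a free parameter). Timepoints are i.i.d. by default; an
  optional AR(1) coefficient adds temporal autocorrelation without changing
  the cross-sectional covariance (innovations scaled by sqrt(1 − a²)). Band
  limits, hemodynamics, motion and missing data are deliberately not
  modelled: Pearson correlations are the only statistic consumed downstream.
* **Background covariance.** A one-factor (global-signal-like) model: every
  ROI loads on one latent factor, which gives a uniform pairwise correlation
  at any level in (0, 1) and a positive-definite matrix by construction. A
  naive structure that sets *only* subcortico-cortical entries to a common
  value is positive definite only below 1/sqrt(96·12) ≈ 0.029, far under
  empirically realistic connectivity (~0.2–0.3), which is why the factor
  construction is used. The dopaminergic and cholinergic seed sets carry
  separate background levels (defaults 0.31 and 0.20 at control level), and
  patient sessions are scaled (DA 0.78× OFF, 0.91× ON; ACh 0.85× both) to
  emulate dopaminergic attenuation that levodopa partially restores.
  Degenerate parameter choices rescale the subcortical loadings with a
  warning; a planted value that still breaks positive definiteness is
  rejected naming the offending ROI pair.
* **Planted effect.** One cholinergic edge (default: right BF123 to a right
  cortical parcel) has its population correlation overridden: 0.16 in OFF for
  both groups; 0.17 in ON for the resistant group and 0.01 in ON for the
  responsive group. Controls keep the OFF value in both sessions (no session
  effect).
* **Clinical scores.** Baseline tremor is a rounded positive normal
  (mean 4, sd 3, floor 1). The per-subject tremor improvement fraction is
  Beta-distributed, moment-matched per group to mean ± sd 0.27 ± 0.24
  (resistant) and 0.92 ± 0.13 (responsive); the ON score is the rounded
  remainder. Because baselines are small integers, rounding pushes realized
  group means slightly toward the extremes (≈0.35 and ≈0.98 rather than 0.27
  and 0.92); the groups stay well separated, which is what the median split
  consumes. Rigidity, bradykinesia and an axial remainder are generated with
  their own improvement fractions so that sub-scores never exceed the UPDRS
  III totals. Covariates are matched across groups by construction: age
  ~ N(60, 9), education ~ round N(9, 4.4) ≥ 0, gender Bernoulli(0.6 male).
* **Recruitment flow.** Extra recruits can be planted with exclusion flags
  (lacunar infarction, ON-state baseline, no baseline tremor, no MRI, high
  motion); the filter removes them in that order and logs the arithmetic
  chain. Excluded recruits carry no imaging sessions.

What passing tests on this cohort do **not** show about real data: the
simulator has no between-subject variance in the true connectivity of an
edge (every subject in a group shares one population correlation), no
spatial structure beyond the single factor, no scanner or motion artefacts,
and integer-valued clinical scores only through rounding. Cross-sectional
connectivity SDs in real cohorts (~0.17–0.28) are therefore between-subject
dominated, whereas here they equal the Fisher sampling SD 1/sqrt(T − 3)
≈ 0.07.

## Change rates

Edge functional reactivity is (z_ON − z_OFF) / max(|z_OFF|, 1e−6). The
denominator floor keeps the 1152-column design matrix finite when a baseline
connectivity is numerically zero (floored entries are flagged rather than
dropped, since the selection step needs complete columns); extreme but finite
change rates are retained, as they are a genuine feature of this statistic.
Tremor responsiveness requires a positive baseline; subjects without baseline
tremor are excluded upstream. The even-n median is the midpoint of the two
central order statistics.

## Stability selection

Each of `n_iter` (default 500) iterations draws a stratified subsample —
floor(0.8 · group size) per group, without replacement (19 + 22 = 41 at the
reference sizes 24/28) — then standardises features with subsample
statistics, builds a 100-point log-spaced penalty grid from λ_max
(= max_j |x_jᵀ(y − ȳ)|/n, the smallest penalty with an all-zero solution)
down to 0.001 λ_max, picks the penalty by stratified 10-fold cross-validated
held-out binomial deviance, refits on the whole subsample, and tallies which
coefficients are nonzero. Frequencies are tallies divided by `n_iter`; edges
at or above the 60% threshold are selected. Iteration seeds are spawned from
the master seed via `numpy.random.SeedSequence(seed).spawn(n_iter)`, so runs
are bitwise reproducible and any single iteration can be replayed.

**Penalty rule.** Both standard cross-validation conventions are
implemented: the deviance-minimising penalty (`cv_rule="min"`) and the
one-standard-error rule (`cv_rule="1se"`, default) — the largest penalty
whose mean deviance is within one between-fold standard error of the
minimum. The 1-SE rule is the default because the minimum-deviance rule
over-selects in this regime: with permuted labels (52 subjects, 50 noise
features, 100 iterations) some chance-correlated feature exceeds the 60%
cutoff in roughly a fifth of replicate runs under "min" (an equivalent
R cv.glmnet loop behaves the same), while under the 1-SE rule fewer than one
replicate in ten does. With a planted feature of standardized effect
d = 1.5 among 383 noise features at n = 24/28, both rules select the planted
feature first with frequency typically ≥ 0.6.

**Solver.** The L1-penalised logistic path minimises mean negative Bernoulli
log-likelihood + λ‖β‖₁ (intercept unpenalised) by IRLS with weighted
coordinate descent: warm starts down the grid, coordinate updates restricted
to the active set, candidate features admitted through a vectorised KKT
screen, weights floored at 1e−6, inner convergence when the largest
weighted squared coefficient change falls below `tol` (default 1e−9), outer
convergence in coefficient space at 1e−10. The path terminates early once
the fit explains 99% of the null deviance or saturates n nonzero
coefficients — beyond that point smaller penalties only chase a diverging
separable solution. At λ ≥ λ_max all slopes are exactly zero by the
soft-threshold condition; at λ → 0 on non-separable data the solution matches
the unpenalised maximum-likelihood fit (verified against statsmodels to
1e−4 and against R glmnet on a shared grid to 5e−4).

**A note on recoverability.** Under the default calibration the planted
edge's change-rate contrast between groups is only d ≈ 0.8 despite the large
connectivity contrast (ON 0.17 vs 0.01), because |z_OFF| ≈ 0.16 is barely
two sampling SDs from zero at T = 200 and the ratio statistic is
consequently heavy-tailed (real cohorts show the same: change-rate SDs an
order of magnitude above their means). Selection frequency for the planted
edge therefore varies strongly across cohort draws (0.02–0.6 over seeds) and
its top rank is not guaranteed; recovery becomes reliable only at scan
lengths several times longer than a typical session. This is an honest
property of the change-rate statistic, not of the selection machinery — the
d = 1.5 synthetic benchmark above is recovered reliably.

## Group statistics

* "Regressed out" covariates enter the GLM directly as design columns for
  group comparisons (so with no covariates the test reduces exactly to the
  pooled two-sample t), but act as prior residualization for the mixed model
  and the partial correlation, matching each analysis's usual formulation.
  Zero-variance covariates are dropped with a warning; aliased columns are
  an error naming the column.
* Normality gates (for the paired t vs Wilcoxon choice and the two-sample t
  vs Mann–Whitney choice) use the Kolmogorov–Smirnov test with estimated
  parameters (Lilliefors critical values) at α = 0.05; samples under 4
  observations or with zero range take the nonparametric branch. All-zero
  paired differences are degenerate and reported as p = 1.
* The mixed model has fixed effects group, status and group × status and a
  per-subject random intercept, fitted by REML; the interaction is a Wald
  test under the normal approximation (no degrees-of-freedom correction —
  with ~100 observations the difference from a t reference is negligible).
  In the balanced two-occasion design the interaction estimate equals the
  difference of the group mean ON−OFF differences exactly. A singular fit
  falls back to a two-sample t test on per-subject differences, flagged.
  Simulation at the reference magnitudes (between-subject SD 0.17, session
  residual SD 0.10 — i.e. total per-session SD ≈ 0.20 with ICC ≈ 0.74 —
  shift −0.15 in one group, n = 24/28) gives ≥ 80% power with a null
  rejection rate within [0.03, 0.07].
* Partial correlation residualizes both variables on the covariates by least
  squares and refers r to a t distribution on n − 2 − k degrees of freedom
  (verified against pingouin).
* Chi-square tests are Pearson, without continuity correction. Bonferroni
  correction is applied exactly where the design calls for it: the selected
  edges (α/m, e.g. 0.05/2 = 0.025 for two edges) and the two network-mean
  comparisons; everything else runs at raw α = 0.05.

## Pipeline and reproducibility

One master seed drives everything: the simulator and selection seeds are
derived via `SeedSequence(master).generate_state(2)` (kept below 2³¹).
Tabular outputs are CSV/TSV with floats at 17 significant digits; reading
back with round-trip parsing restores values exactly. The manifest lists the
configuration echo, package version and SHA-256 checksums of every output, so
a bundle can be re-run and verified from the manifest alone; no timestamps
enter any output, making reruns bitwise identical. Default problem sizes in
the test-suite and acceptance-script simulations (e.g. 100 selection
iterations rather than 500, miniature cohorts for structural checks) were
chosen as the smallest sizes at which the corresponding statistical claims
are stable.

## Known limitations

* ROI time series are consumed as given; atlas handling, denoising and
  motion control are upstream concerns.
* The 60% selection threshold is taken as fixed by design, with no
  per-family error-rate calibration, and no elastic-net mixing or
  complementary-pairs variant is provided.
* The simulator's fixed within-group connectivity understates between-subject
  variability (see above), which mainly affects how well change-rate effect
  sizes transfer from simulation to real cohorts.
* Alternative responder definitions (absolute-change thresholds, MDS-UPDRS
  variants) are out of scope.
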