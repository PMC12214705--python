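# Methods

`braindiff` implements, as a tested pipeline on fully synthetic cohorts,
an analytic chain that links polygenic risk, regional sexual
differentiation of functional connectivity (FC), physiological aging,
pubertal development and change in psychiatric symptoms.  This note
documents the models, the synthetic-data design, the numerical choices,
and what the tests do and do not establish.

## The analytic chain

1. **Sexual-differentiation template.**  In an adult reference cohort,
   every FC edge (Fisher-z transformed Pearson correlation between
   parcel time series, run-averaged, diagonal excluded) is regressed on
   biological sex (coded +1 male / −1 female) together with demographic,
   psychopathology, motion and cognition covariates.  The t statistic of
   the sex coefficient per edge forms an R×R template; positive entries
   mark coupling that is consistently stronger in males.

2. **Regional differentiation profiles.**  For each adolescent, region
   i's profile entry is the Spearman correlation between row i of their
   FC matrix and row i of the template, over the R−1 off-diagonal edges
   (average ranks for ties; the undefined self-edge is excluded).
   Positive values mean a more masculine regional coupling pattern.
   Profiles are subsequently residualized for mean framewise
   displacement.

3. **Biological age.**  A Gompertz proportional-hazards model
   h(t | age, x) = exp(b0 + b_age·age + Σ b_k x_k)·exp(γt) is fitted by
   maximum likelihood (administrative censoring at horizon τ, default
   10 years) on a young-adult mortality cohort with eight blood-chemistry
   markers (MCV, RBC, RDW, WBC, lymphocyte %, monocyte %, HbA1c, total
   cholesterol).  The implied death probability
   M = 1 − exp(−exp(lp)(e^{γτ}−1)/γ) is inverted through an age-only
   submodel fitted on the same cohort,
   a = (ln(−γ′ln(1−M)/(e^{γ′τ}−1)) − b0′)/b_age′,
   giving the chronological age at which the subject's risk would be
   normal in the reference group.  Acceleration is the OLS residual of
   this biological age on age and sex.

4. **Pubertal indices.**  Hormonal adrenarche/gonadarche are built
   within sex from salivary DHEA, testosterone and estradiol:
   residualize on saliva-quality covariates (plus menstrual-cycle fields
   in girls), z-score within sex, combine (girls' adrenarche = mean of
   z-DHEA and z-testosterone; boys' adrenarche = z-DHEA; gonadarche =
   z-estradiol in girls / z-testosterone in boys), re-standardize within
   sex, pool.  Self-report indices average the sex-specific Pubertal
   Development Scale item sets, with a mean-of-available-items rule for
   sporadic missingness and an optional parent-report fallback when a
   construct is entirely missing.  Symptom change per scale is
   z(T3) − z(T2) with z-scores computed within wave on the analysis
   sample.

5. **Cross-validated CCA.**  Canonical weights are estimated by SVD of
   the whitened cross-covariance (equivalent to the generalized
   eigenproblem Σxx⁻¹ΣxyΣyy⁻¹Σyx); columns are standardized internally
   and eigenvalues clipped at a relative 1e-10 floor, which doubles as a
   pseudo-inverse regularization when n ≤ p_x + p_y.  In k-fold
   cross-validation (default k = 10), confound regressions,
   standardization and weights are fitted on the training folds and
   applied unchanged to the left-out fold; the first predicted variate
   pair is concatenated over test folds (fold signs aligned to the first
   fold by weight-vector dot product) and summarized by r_CV.
   Significance comes from re-running the *entire* CV loop — confound
   residualization included — on row-permuted Y,
   p = (#{|r_null| ≥ |r_obs|}+1)/(n_perm+1).  Loadings are correlations
   between observed variables and the concatenated predicted variate,
   with percentile bootstrap CIs (99% by default); a variable is robust
   when its CI excludes zero.

6. **Condition-wise PLS.**  With T1/T2 differentiation profiles as two
   conditions, the correlation blocks corr(behavior, brain_c) are
   stacked row-wise into a (C·B)×R matrix and decomposed by SVD: one
   unit-norm brain salience per latent variable shared across
   conditions, condition-specific behavior saliences, and covariance
   explained s_l²/Σs².  Discovery inference permutes behavior rows with
   one ordering shared across conditions; reliability uses subject
   bootstrap with per-resample sign alignment, flagging parcels with
   |salience/bootstrap SD| > 2.75 (≈ a 99% normal interval).  The
   cross-validated test weights test-fold parcel and behavior data by
   training-fold saliences, applies the SVD to the condition-wise
   correlation of the weighted matrices concatenated over folds, and
   permutes behavior rows with the full procedure re-run per draw (see
   "Numerical choices").

7. **Axis alignment.**  Parcel maps are compared to the
   sensorimotor-association gradient by Spearman correlation, with
   significance from hemisphere-paired spin permutations: one uniform
   random rotation applied to left-hemisphere centroids and its mirror
   image (reflection through the sagittal plane) to the right, followed
   by greedy one-to-one matching of rotated to original centroids,
   closest pairs assigned first.  Two-sided p with the +1 convention.

8. **Serial mediation.**  Model-81 topology — X→M1→{M2, M3}→Y with a
   common covariate set in all four OLS equations, HC3
   heteroscedasticity-consistent standard errors, pre-fit z-scoring of
   analysis variables, and optional pre-adjustment of every variable for
   baseline pubertal measures.  Five specific indirect effects (three
   simple, two serial) are products of path coefficients; the identity
   total = direct + Σ indirect holds exactly on OLS coefficients fitted
   with a shared covariate set.  CIs are case-resampling percentile
   bootstrap (95%), z-scoring done once on the original sample.

9. **Phenotype maps.**  Partial Spearman correlations (rank-transform
   all variables, residualize the ranks on the dummy-coded confound
   design, Pearson on residuals) between each region's differentiation
   profile and 13 measures — nine DSM-oriented symptom scales, BMI,
   financial deprivation, self-reported adrenarche and gonadarche —
   yield 13 maps whose overlap with the PLS brain map is tested across
   parcels with spin-based nulls.

## Synthetic cohorts

The generators produce every input the chain needs, with planted ground
truth, under a single integer seed (bitwise-reproducible).

* **Geometry.**  Fibonacci layouts on each half of the unit sphere
  (left x < 0, right x > 0); the default gradient is the rank of the
  centroid z coordinate — spatially smooth, so spin nulls face realistic
  autocorrelation.  Gradient ranks are min-max normalized to [0, 1]
  internally so effect sizes do not scale with parcel count.

* **Reference adults.**  FC = shared base connectome + sex offset +
  edge noise.  The male-minus-female mean difference on edge (i, j) is
  `sex_effect_scale · (a_i + a_j)` with `a` the unit-normalized
  gradient.  The base connectome has iid edge means (0.3 ± 0.15) so
  every row has approximately equal variance; heterogeneous row
  variances would distort similarity profiles region-dependently.

* **Adolescents.**  The causal chain is standardized linear-Gaussian:
  brain = g·PRS + ε, physio = h·std(brain) + ε,
  Δsymptom = q·std(physio) + d·PRS + ε, with path coefficients
  (g, h, q, d) and layer noise SDs from the configuration (defaults
  0.5/0.5/0.5/0 and residual SDs 0.87, making each path the implied
  correlation between consecutive standardized latents).  The package
  exposes the closed-form implied PRS→symptom correlation for oracle
  checks.  Individual masculinization (sex offset + brain latent) loads
  *multiplicatively* on edges, `masc · a_i·a_j`: a within-row slope
  proportional to a_i is what makes regional profiles differentiate most
  in high-gradient regions; an additive a_i term is constant within a
  row and cannot produce axis-loaded profiles.  Hormones, PDS items,
  CBCL scales (means and SDs follow the published cohort summary
  tables), biomarkers, BMI, deprivation, medical-history counts and all
  confounds are derived from the latents with configured noise.  Each
  disorder's polygenic score uses its own independent SNP panel
  (binomial dosages at configured allele frequencies, no linkage), so
  non-target scores are genuine null exposures.  Estradiol exists only
  for girls; voice/facial-hair items only for boys, breast/menarche
  items only for girls.

* **Mortality cohort.**  Event times by inverse transform from the
  Gompertz law, censored at the horizon.  The planted coefficients
  (b_age = 0.25/yr, standardized biomarker log-hazard effects of 0.5,
  γ = 0.5/yr, ≈55–60% events at n = 5000) deliberately describe a
  *well-identified* regime: per-coefficient relative standard errors of
  a few percent and an age slope strong enough to dominate the frailty
  distortion of the marginal age-only fit, so that coefficient recovery
  within 10% and mean-biological-age anchoring within one year are
  statistically meaningful checks.  Real population values (γ ≈ 0.09,
  deaths rare before 40) would leave γ and the small coefficients
  unidentifiable at this sample size; the generator trades demographic
  realism for testability and says so here.

* **What the generators do not emulate.**  BOLD autocorrelation spectra
  and scanner artifacts (time series, when requested, are Gaussian draws
  with the target correlation structure); linkage disequilibrium and
  genotype imputation; family structure; item-response measurement
  models for questionnaires; competing risks of death.  Passing tests
  therefore demonstrate that the *statistical machinery* is correct and
  calibrated, not that effect sizes on real cohorts will match.

## Numerical choices

* Fisher transform clips |r| at 1 − 1e-7; the FC diagonal is masked
  (NaN), never imputed.
* The motion band-stop (0.31–0.43 Hz respiratory band) is an order-2
  Butterworth applied forward-backward (zero phase); at TR = 0.8 s it
  attenuates in-band sinusoids below 2% amplitude and passes 0.05 Hz
  within 0.01%.
* Nuisance regression and residualization verify residual/design
  orthogonality on every call (columns whose residual norm vanishes
  relative to the input are orthogonal by convention); rank-deficient
  designs fall back to the pseudo-inverse with a warning.
* Sign conventions: CCA/PLS component signs are fixed by making the
  largest-|weight| element positive; CV fold weights are aligned to the
  first fold; bootstrap resamples align to the original salience.
* The Gompertz likelihood is maximized by L-BFGS-B with an analytic
  gradient, standardized covariates, and log-γ bounded in
  [ln 1e-4, ln 5]; convergence failures raise with the gradient norm.
  Biological-age risks that saturate numerically are nudged into the
  open interval before inversion.
* The PLS cross-validated null re-runs the complete four-step procedure
  (training saliences refitted) per permutation rather than reusing the
  observed saliences.  With overlapping training folds the fixed-weight
  shortcut leaves the learned weights aligned with the full-sample noise
  and rejects a true null ≈13–18% of the time at α = 0.05 in our
  simulations; refitting restores exact exchangeability (measured
  rejection 4.5%).  The CCA permutation test re-runs its CV loop for the
  same reason.
* Spin matching is greedy closest-pair-first.  Spun maps retain ≈75–85%
  of a smooth map's Moran's I at R = 60–200 (one-to-one matching at
  finite parcel density is lossy); the spin p-value is calibrated at
  nominal level for Gaussian-field maps of moderate smoothness
  (length scale ≈0.3 rad), and becomes anticonservative for extremely
  low-rank fields (e.g., purely linear-in-coordinate maps), a known
  regime limitation of rotation-based nulls.
* A wave-constant symptom scale is dropped from change scoring with a
  warning rather than aborting the remaining scales.
* Motion-exclusion thresholds are strict inequalities (mean FD exactly
  at the cutoff excludes).

## Desk-scale problem sizes

Defaults are sized for a laptop: cohorts of 400–500 subjects, 100
parcels, 500–2000 resamples, with configuration flags scaling to the
five- or six-figure resampling depths a production run would use.  The
test suite runs calibration at 200 replicates × 500 permutations
(n = 60–80 subjects per replicate), recovery at n = 500 subjects /
R = 100 parcels with 300–500 resamples, and mortality-model recovery at
n = 5000.

## Known limitations

* The age-only Gompertz submodel is a frailty-contaminated marginal; its
  MLE is not the age part of the full model, so biological-age anchoring
  is approximate (within a year under the default design, worse if
  biomarker effects are inflated relative to the age slope).
* Profiles scored against a single template realization share a fixed
  per-region chance alignment between the base connectome and template
  noise; per-region null means are therefore only unbiased across
  template realizations, not conditionally on one.
* The spin null is approximate by construction (rotation + re-matching);
  see above for its calibration envelope.
* Discovery (unresidualized) and cross-validated (residualized)
  estimates answer different questions; the pipeline reports both where
  the workflow does.
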