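# Methods

This note documents the statistical procedures implemented in `neurodyad`,
the assumptions behind the synthetic-study generator, the numerical choices,
and the limitations a user should know before trusting a green test suite.

## 1. Social network quantities

The raw survey instrument is a directed binary nomination matrix (row =
nominator).  Two undirected graphs are derived: the *reciprocal-tie* graph
(edge only when both directions exist — the default analysis graph) and the
*any-tie* graph.  Social distance is the BFS geodesic on the chosen graph,
computed on the **full cohort** and only then restricted to the scanned
subsample, since shortest paths legitimately run through unscanned cohort
members.  Distances of 4 or more, and pairs with no connecting path, collapse
into a single "4+" category (cap configurable).  The diameter of a
disconnected graph is reported as the maximum finite geodesic, with a
`connected` flag in the output.

Summary statistics: density `|E|/C(N,2)` per graph; *total reciprocity* =
P(a directed nomination is returned) = 2·mutual/directed; *dyad-level
reciprocity* = P(mutual | any tie).  Two algebraic identities hold exactly
and are tested: dyad reciprocity = density_rec/density_any and total
reciprocity = 2·d_rec/(d_rec + d_any).

## 2. Dyadic similarity

Per dyad and ROI, similarity is the Pearson correlation of the two subjects'
concatenated ROI-mean series.  Zero-variance series are treated as missing
(with a warning), not as r = 0.  Processing order is fixed: **impute**
missing entries with the ROI's mean correlation over observed dyads (imputed
cells flagged and retained downstream), then **z-score** each ROI across
dyads, then form the **composite** as the volume-weighted mean of z-scores
(equal-weight mode available; the two agree exactly when volumes are equal).
The z-score uses the sample SD (ddof = 1); a population-SD mode exists.  No
Fisher transform is applied: normalization across dyads replaces it.

## 3. Dyad-level regression and inference

Ordered model: proportional odds with parameterization
`logit P(Y<=k|x) = tau_k − x'b`, so a negative similarity coefficient means
similarity pulls dyads toward shorter distance.  Binary model: standard
logistic regression of the friendship indicator (distance category 1), whose
similarity coefficient is positive under the same effect; a two-category
ordered fit equals the binary fit with the sign flipped, which is tested.
Predictors are standardized (mean 0, SD 1) by default.

Fitting: the ordered likelihood is maximized by L-BFGS-B with an analytic
gradient in a log-threshold-difference parameterization that keeps the
thresholds ordered; thresholds start at the logits of the cumulative category
frequencies and slopes at zero; tolerance 1e-8, 200 iterations max.  The
binary model uses Newton–Raphson with step halving.  Non-convergence —
including separation, detected as a residual gradient or a parameter
exceeding 30 on the logit scale — raises an explicit error with diagnostics;
it is never silently truncated.

Inference: per-observation scores and the observed information (finite
differences of the analytic gradient for the ordered model; analytic
elsewhere) feed a CGM-style multi-way sandwich,
`V = V_m1 + V_m2 − V_dyad`, clustering on each dyad member with the dyads
themselves as the intersection clusters.  Negative eigenvalues produced by
the subtraction are clipped to zero.  No small-sample multiplier is applied
by default (`small_sample=True` adds G/(G−1) per component); p-values are
two-tailed normal-reference Wald.  Under singleton clusters the estimator
reduces exactly to the HC0 sandwich (tested), and it matches an independent
OLS implementation of two-way clustering up to that implementation's fixed
finite-sample multiplier.

Model comparison uses the likelihood-ratio test (`2Δℓ ~ χ²(Δdf)`) for nested
fits on identical data.  Per-ROI analyses fit one ordered model per ROI
(that ROI's z-similarity plus all controls) and apply Benjamini–Hochberg
step-up FDR across the ROIs that converged; non-converged ROIs are reported
with NaNs and excluded from the FDR family with a warning.  Deviation-coded
category contrasts come from an OLS of the composite on a full set of
category indicators plus mean-centered controls; the estimate for category k
is its adjusted mean minus the unweighted mean of the other categories'
adjusted means, with CIs from the same two-way clustered sandwich.

The odds interpretation helper maps a logit coefficient to
`100·(exp(b) − 1)` percent change in odds per SD of the predictor.

## 4. Nonparametric and permutation tests

Group-vs-rest comparisons of composite similarity use the two-sample
two-sided KS test (asymptotic p; sample sizes here are in the hundreds) and
the Wilcoxon rank-sum test with W = rank sum of the first group.  The
rank-sum null is exact — a subset-sum dynamic program over doubled midranks,
which handles ties — whenever n1·n2 ≤ 400, and otherwise a normal
approximation with tie and continuity corrections.  Exact two-sided p is
2·min(lower tail, upper tail), capped at 1.

The network permutation test holds the network topology (hence the multiset
of dyadic distances) fixed and draws uniform random bijections of subjects
onto network positions; each dyad's distance category is re-derived while its
similarity value stays attached to the subject pair.  Per-category p-values
are two-sided around the null mean with the add-one correction
`(1 + #extreme)/(n_perm + 1)`; one-sided modes are available.  This test is
exactly valid when subjects are exchangeable, and its measured type-I error
on null synthetic data is within the binomial band (see tests).

## 5. Social-distance classification

Features are the per-ROI z-scored similarities (as produced in §2, i.e.
scaled across *all* dyads; the resulting mild transductive leakage of scaling
statistics replicates the emulated procedure and is noted here).  The
pipeline: stratified outer folds (default 8); within each training fold,
minority categories are oversampled to the majority size by repeated full
random passes without replacement (every original example retained; no
example duplicated twice before all are duplicated once); C for a linear SVM
is tuned on inner stratified folds (default 8) over a log grid (default
10^-3..10^3, 7 points; ties break to the smallest C), with oversampling
applied only to inner training splits; the tuned SVM is refit on the
oversampled training fold and predicts the held-out dyads.  One-vs-rest uses
a liblinear SVM; one-vs-one uses the libsvm linear kernel.  Reported:
row-normalized confusion matrix, pooled accuracy over all held-out
predictions, and the unweighted mean of per-fold accuracies (the aggregation
is ambiguous in the emulated study, so both are emitted).  Significance:
the full pipeline is re-run with training labels shuffled independently
within each training fold; p = (1 + #{null ≥ observed})/(n_perm + 1).
Dyads sharing a subject may occupy both train and test folds (as in the
emulated design); a stricter subject-disjoint mode is a config flag.

Chance level for the 4-way problem is 0.25 on balanced test data because
oversampling equalizes training class counts; the label-permutation null is
centered there (verified).

## 6. The synthetic-study generator

The generator emulates the study design, not the biology:

* **Demographics** — gender (32% F), four ethnicity and five nationality
  categories with one majority group each, ages 25–32 (mean ≈ 28),
  7% left-handed.  Values chosen once to mirror the emulated cohort's
  published marginals.
* **Network** — each dyad's two directed nominations are a mixture of one
  shared and two independent Bernoulli draws; the mixing weight is solved
  per dyad so that dyad-level reciprocity equals its target (default 0.309)
  at the configured directed rate (default 0.0955).  Dyad rates are modulated
  by gender assortativity (assortativity 1 confines ties to same-gender
  pairs) and by a latent-space kernel: subjects hold uniform 2-D positions
  and tie probability decays as a Gaussian in latent distance
  (scale 0.15, per-dyad cap 0.4, renormalized to preserve the mean rate).
  The kernel exists because a homogeneous random graph at this density has
  diameter ≈ 4 and virtually no distance-4 dyads; with it, the simulated
  cohort reproduces the emulated regime — any-tie density ≈ 0.146, dyad
  reciprocity ≈ 0.31, reciprocal diameter 5–6, and a scanned-dyad category
  split near (5%, 32%, 46%, 17%).
* **Time series** — `x_{i,r}(t) = c_r(t) + Σ_k w_{i,k} f_{k,r}(t) + σ ε`,
  with subject weights drawn from N(0, C), `C = ρ^{d(i,j)}` repaired to the
  nearest unit-diagonal PSD matrix by eigenvalue clipping.  Expected
  inter-subject correlation is `(c² + K w² ρ^d) / (c² + K w² + σ²)` —
  strictly decreasing in distance for ρ < 1, flat for ρ = 1 or zero
  component variance (the two null worlds).  Defaults: K = 5, ρ = 0.5,
  σ = 1, c = 0.5, T = 1000, R = 80; ROI dropout is i.i.d.
  Bernoulli(0.0092) per (subject, ROI), matching the emulated coverage-loss
  rate.  All draws descend from one master seed through named substreams, so
  stages regenerate independently and bit-identically.

What the generator does **not** emulate: hemodynamics, autocorrelated or
ROI-specific noise spectra, heterogeneous ROI reliabilities, any spatial
structure among ROIs, or content-driven response differences.  Consequently
a green test establishes that the *procedures* behave as specified on data
with the stated covariance structure — not that the scientific effect exists
in any real population, and not that effect sizes transfer.

Planted-effect tests use two stated worlds: the default world above, and a
"strong gradient" world (K = 40, ρ = 0.7, σ = 0.3, c = 0.3, T = 600) for
classifier power checks, chosen because the planted signal is essentially
one-dimensional (all ROIs share the same latent trait correlation), which
caps 4-way separability under the default parameters.

## 7. Runtime scaling of the test suite

Monte-Carlo suites run the generator at reduced size purely for runtime:
null-calibration datasets use T = 150, R = 20 (the dyad-level structure — 42
scanned subjects, 861 dyads — is preserved wherever a claim depends on it),
the classifier chance-level suite uses balanced 160-dyad sets with a 3-point
C grid and 4 folds, and permutation counts are reduced to 200.  These sizes
were fixed before the corresponding assertions were finalized and are not
tuned to outcomes.

## 8. Known limitations

* **Few-cluster Wald inference (documented red test).**  The two-way
  clustered Wald test of the similarity coefficient over-rejects under the
  null at the emulated scale: measured type-I error ≈ 0.09 with fully
  independent dyads and ≈ 0.14 under the shared-signal null, versus the
  nominal 0.05, over 200 simulated datasets.  The sandwich itself is correct
  (it matches an independent implementation exactly); the miscalibration is
  the well-known anti-conservativeness of cluster-robust variance estimators
  with ~42 clusters, amplified by dyadic overlap, under a normal reference
  with no small-sample correction — exactly the inference recipe specified.
  The corresponding acceptance test is left failing on purpose with this
  analysis in its docstring; the LR test and the network permutation test
  are calibrated and green.  Users wanting calibrated per-coefficient
  inference at this scale should prefer the permutation test.
* The proportional-odds assumption (common slope across cumulative logits)
  is imposed, not tested.
* Exact rank-sum enumeration is limited to n1·n2 ≤ 400; beyond that the
  corrected normal approximation is used.
* The per-dyad tie-probability cap (0.4) means extreme `tie_base_rate`
  values between the cap and 1 are attained only in the mean, not per dyad.
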