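# Methods

`phenostrat` implements a population-stratification discovery analysis for
deeply phenotyped cohorts: it embeds a curated participants × variables
phenome matrix with a data-collection-site-conditioned variational
autoencoder (CVAE), ranks the latent components as sources of population
variation, attributes each component to its driving phenotypes, and
validates the multidimensionality of the socioeconomic-status (SES) signal
by predicting geography from SES-only component scores. Because the cohort
data this kind of analysis targets is access-controlled, the package ships
a synthetic phenome generator with planted ground truth; every stage is
exercised against what was planted.

## The model

Let X be the curated phenome matrix and C the one-of-n site indicator. The
CVAE assumes X arises from a latent variable Z with standard-normal prior,
through a decoder p_θ(X | Z, C); an encoder q_φ(Z | X, C) — a diagonal
Gaussian with mean μ(x, c) and variance σ²(x, c) — approximates the
posterior. Training maximizes the evidence lower bound

    L(θ, φ) = E_q[log p_θ(X | Z, C)] − β · KL[q_φ(Z | X, C) ‖ N(0, I)]

with the Gaussian reconstruction term implemented as summed squared error
and the KL in closed form, 0.5 Σ(μ² + σ² − log σ² − 1). β defaults to 1
(the plain ELBO). Conditioning on site is the mechanism by which the
latent space is relieved of encoding the site batch structure: the site
vector is appended to the encoder input and to z before decoding.

Both encoder and decoder have one hidden layer (ReLU by default, linear
output on the decoder). Some architectures first project X to a PCA
front-end (fit on the training split only); reconstructions are always
mapped back through the front-end so errors are measured in the curated
variable space. The networks are implemented directly on NumPy with
hand-derived backpropagation and Adam — at these sizes (hundreds of inputs,
≤ a few hundred hidden units) this is faster to run and simpler to audit
than a deep-learning framework, and the gradients are verified against
finite differences in the test suite.

**MSE convention.** Reconstruction error is summed over curated variables
and averaged over participants, in the ambient (front-end-inverted) space.
This makes architectures with different front-end sizes and the PCA
baseline directly comparable; on standardized data a zero-predictor scores
approximately the number of variables.

**Determinism.** Every stochastic step (weight init, minibatch order,
reparameterization draws, splits, CV folds) is driven by an explicit seed.
Scores and reconstructions use the posterior mean by default; one-sample
mode is available behind a seeded RNG.

## Curation protocol

Raw tables pass through, in order: retention of collection events covering
≥ 95% of baseline participants; pruning of variables populated for < 80% of
participants; removal of near-constant variables (most frequent value
> 99% of non-missing entries — one fixed reading of an ambiguous rule,
recorded in the report so it can be swapped); recoding of configurable
non-compliance sentinel codes to missing; one-hot encoding of discrete
variables into per-level indicators that inherit the parent's category;
median (continuous) / mode (indicator) imputation; winsorization of
continuous columns at |z| = 4 followed by z-scoring.

Winsorization iterates detection and replacement to a fixed point: a first
replacement shrinks the column SD, which can expose further entries, so a
single pass would leave values beyond 4 SD of the final statistics.
Iterating makes the bound hold under the final standardization and makes
curation idempotent. A corollary of mean/SD-based detection worth knowing:
a lone extreme value in a very small sample can inflate the SD enough to
mask itself; this is a property of the protocol's definition, not of the
implementation. Standardization statistics come from the full curated
sample by default (curation precedes splitting); a train-only mode exists
for leakage-sensitive uses. Indicators are exempt from winsorization
(bounded by construction) and from the near-constant rule (their parents
were already screened; this also preserves idempotence).

## Component ranking, attribution, profiling

- **Scores** are encoder posterior means per participant.
- **Loadings** are Pearson correlations between component scores and each
  curated variable over the test split; *weight strength* is |r|.
  Zero-variance variables receive loading 0 with a flag rather than an
  error, keeping downstream thresholding total.
- **Ablation ranking** decodes from each component alone (all other latent
  coordinates zeroed, conditioning untouched) and orders components by the
  resulting test MSE, ascending. For a linear decoder with orthogonal
  columns this provably ranks by component variance × column norm; the
  closed form is a test oracle.
- **Elbow** selection finds the point of the sorted ablation-MSE curve
  farthest from the chord joining its endpoints; if that point lies above
  the chord (the curve jumps onto a plateau of uninformative components)
  the cut stops just before it, otherwise it is included. A manual override
  is first-class, because at full scale this cut is a judgment call. An
  exactly linear curve returns 1 with a degeneracy flag.
- **Thresholding** retains each variable only in its top ceil((1−p)·K)
  components by weight strength (p = 0.95: exactly 5 of 100, 1 of 20),
  ties broken toward the lower component index.
- **Profiles** average weight strength over retained variables per
  (component, category) and report the retained share of each category;
  the SES overlap report performs exact set algebra (all intersection
  cardinalities, unique sets) over the retained Socioeconomic measures of
  the chosen components.

## State prediction

SES-only component scores are dot products of a participant's curated
Socioeconomic measurements with the component's retained (masked) SES
loadings; an unmasked mode using all SES loadings exists for sensitivity
checks. One-vs-rest logistic regression with the default L2 penalty (C = 1,
no class weighting — both configurable) under stratified 10-fold
cross-validation pools out-of-fold predictions into a row-percentage
confusion matrix; coefficients are averaged over folds per state, and the
most influential component per state is the argmax of |mean coefficient|.
Chance level is 100/n_states (5.88% at 17 states). A label-permutation
helper estimates the null accuracy band; note the null centres on the
majority-class share, not necessarily on 100/n_states.

## Synthetic cohort generator

The generator emulates the statistical features that matter to the
pipeline, at a scaled-down default of 2,000 participants × 300 variables
(the motivating cohort is ~12,000 × ~13,600): a rank-5 linear factor model
with factor variances (16, 8, 4, 2, 1) — adjacent ratios of 2, well
separated; dense Gaussian loadings with the Socioeconomic block loading
3× more strongly on the first ("SES") factor; additive per-site offsets
(21 sites, SD 0.5); unit Gaussian noise; an odd squashing nonlinearity
a·tanh(·/a) with a = half the column SD on 25% of links (saturating ~2σ
excursions — the regime where a nonlinear decoder can beat PCA); 30% of
variables ordinalized into 2–3 levels by quantile thresholds; 5%
missingness, completely at random (the minimal assumption; it keeps the
pruning rules interpretable); 0.2% multiplicative 8× outliers so
winsorization is exercised; and 17 state labels shifting the SES-factor
mean by shift·u_s with u_s equally spaced in [−1, 1].

What it does **not** emulate: realistic per-variable marginals, skip-logic
and structured missingness, longitudinal dependence between collection
events, genotypes. Passing tests therefore demonstrate that the machinery
recovers planted structure of this kind, not that it would recover any
particular real cohort's structure.

## Experiment design choices

- **Linear-limit check.** On a noiseless rank-5 cohort PCA's hold-out
  error is at machine precision, so "matching PCA" is stated in
  unexplained-variance fractions (MSE / zero-predictor MSE): the linear,
  β→0, unconditioned model must come within 0.10 of PCA's fraction (it
  lands near 3×10⁻⁴ in practice).
- **Factor recovery** uses the linear-activation model trained to
  convergence without early stopping. The ReLU model reconstructs as well
  but leaves the latent basis rotationally entangled with the planted
  factors; for a linear decoder the diagonal-posterior KL term breaks the
  rotational symmetry of the objective, and the converged model aligns
  with the planted factors (greedy-matched mean |r| ≈ 0.96 at the
  2,000 × 300 / 5-factor / 20-latent conditions). Alignment emerges slowly
  — hundreds to thousands of epochs — which is why early stopping is
  disabled for this experiment.
- **Nonlinear advantage** (CVAE beating PCA with 50% squashed links) is
  evaluated at n = 6,000. At n = 2,000 the deep model is overfitting-
  limited (training error below PCA's, hold-out above), which masks a gain
  that is real at the cohort-like sample size; 6,000 is the smallest scale
  at which the comparison is comfortably sample-adequate.
- **Strong state→SES signal** means shift = 8: the between-state spread of
  SES-factor means (2·shift = 16) equals 4 within-state factor SDs. Under
  it, a majority of the 17 synthetic states are predicted above chance;
  with shift = 0 accuracy stays inside the permutation null band.
- **Problem sizes** throughout the tests and the reproduction script
  (600–6,000 participants, 20 latent dimensions, 1–5 replicates) are the
  package's scaled-down stand-ins for the full-scale study design (11,875
  participants, 100 latent dimensions, 25 replicates × 6 architectures).

## Numerical details and degenerate inputs

log σ² is clipped to ±12 for stability; divergence (non-finite loss)
raises immediately with advice to lower the learning rate rather than
continuing. Early stopping monitors the deterministic (posterior-mean)
validation ELBO with patience 10 and restores the best parameters.
Glorot-uniform initialization. Architecture selection excludes diverged
replicates and disqualifies candidates with < 80% successful replicates.
Stratified splitting requires ≥ 3 participants per site; state prediction
requires ≥ n_folds participants per state and names offenders. Ties: in
thresholding, lower component index; in top-phenotype listings, variable
name; in influence attribution, earlier component.

## Known limitations

The ReLU model's components are not identifiable up to rotation — at full
scale, interpretation rests on attribution (loadings and thresholding)
rather than on any claim of disentanglement. The synthetic generator's
single SES factor makes "SES multidimensionality" appear as distinct
retained-measure configurations across components, a weaker analogue of
the real phenomenon. Imputation is marginal (median/mode); model-based
imputation is out of scope. Reconstruction-based ranking measures variance
explained, not scientific importance.
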