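# Methods

## Problem setting

`synthcohort` generates artificial patient cohorts from a single small,
wide clinical table — the high-dimension, low-sample-size (HDLSS) regime
typical of perioperative questionnaires: a few hundred patients, under a
hundred mixed-type features (bounded numerics, comorbidity/medication
flags, ordered categories).  The generated cohort should be
*consistent* (statistically indistinguishable from the source in
marginals and pairwise structure), *confidential* (no artificial record
duplicates or crowds a real patient) and *plausible* (domain experts
cannot tell records apart).  All three properties are measured by the
package itself, on the package's own outputs.

## Data model and preprocessing

A cohort is described by a schema of typed columns: numerical columns with
bounds and an integer-valued flag; binary columns with two ordered levels;
categorical columns with three or more levels.  The tabular processor
encodes a validated cohort into a fully numeric design matrix in
`[0, 1]`: min–max scaling for numerics (bounded, invertible, and matched
to a sigmoid decoder's range — z-scoring was rejected because decoding
would be unbounded), a single 0/1 column per binary, and one-hot blocks
per categorical.  The inverse transform un-scales with the stored
per-column (min, max), clips to the schema bounds, rounds integer-valued
numerics half away from zero, thresholds binaries at 0.5 and decodes
one-hot blocks by argmax with ties broken toward the lowest-index level.
Missing cells are imputed before encoding (median for numerics, mode for
discrete columns) and the imputation counts are logged.  An 85-feature
schema with 19 numerics, 60 binaries and 6 four-level categoricals encodes
to 19 + 60 + 24 = 103 columns.

## The generative model

The core is a variational autoencoder whose latent space carries a
learned Riemannian metric.

**Networks.** Encoder: tanh MLP (default hidden widths 64, 32) mapping a
design row to a posterior mean and log-variance in a `latent_dim = 10`
latent space.  Decoder: the mirrored MLP with sigmoid outputs, so decoded
means always live in `(0, 1)`.

**Reconstruction likelihood.** Mixed, by encoded-column role:

* scaled numeric columns — heteroscedastic Gaussian
  `x_j | z ~ N(m_j(z), sigma_j^2)` with one learned `log sigma_j` per
  column, initialised at the column's marginal sd and clamped to
  `[1e-3, 1]`.  Clinical numerics carry idiosyncratic measurement noise
  whose scale differs per variable by an order of magnitude; a likelihood
  without a dispersion parameter (Bernoulli-type cross-entropies on
  `[0, 1]` values) cannot represent it, and its fitted parameter is not
  the conditional mean, which biases every decoded marginal.  The learned
  `sigma_j` partitions each column's variance into a latent-explained part
  and residual noise; in calibration runs on the synthetic cohort the
  implied marginal sd `sqrt(sd(m_j)^2 + sigma_j^2)` matches the real
  column sd to within a few percent.
* binary and one-hot columns — Bernoulli cross-entropy on the sigmoid
  outputs.

**Objective.** The ELBO with a standard-normal prior, `KL(q(z|x) || N(0, I))`
warmed up linearly over the first half of the epochs.  The warm-up counteracts
posterior collapse, which was observed directly without it (only 2 of 10
latent dimensions active after 300 epochs on the 521 x 103 cohort).

**Riemannian metric.** The inverse metric is a centroid-weighted sum of
PSD lobes with a ridge,

    G^{-1}(z) = sum_i L_i L_i^T exp(-||z - c_i||^2 / T^2) + lambda I,

with temperature `T = 0.8`, ridge `lambda = 1e-3`, and up to 400 centroids
placed at the posterior means of a fixed training subsample.  The factors
are diagonal, `L_i = diag(1/sigma_post,i)`, so each lobe's scale is the
local posterior precision.  Centroids and factors track the encoder by
exponential moving average (rate 0.05 per epoch) and are snapped to the
converged posterior moments after the last epoch.  `G^{-1}` is symmetric
positive definite everywhere (eigenvalues >= lambda) and decays to
`lambda I` far from the data.

**Hamiltonian posterior refinement.** During training the reparameterised
posterior sample can be pushed along the manifold by `n_leapfrog_steps`
(default 3) of generalized-leapfrog integration of
`H(z, p) = U(z) + 1/2 p^T G^{-1}(z) p + 1/2 log det G(z)` with
`U(z) = -log p(x|z) - log N(z; 0, I)` and momenta drawn from `N(0, G(z))`.
The integrator is the implicit (fixed-point) scheme required by a
position-dependent kinetic term; it is time-reversible to 1e-6 and
empirically second-order in the step size (both tested).  Backpropagating
through the integrator needs second-order decoder derivatives, so the
trajectory endpoint enters the loss with a straight-through gradient (the
displacement `z_K - z_0` is treated as constant in backward).  With zero
steps and an identity metric the engine reduces exactly to a vanilla VAE,
and its objective matches an independently written ELBO within 1e-5 (an
oracle-equivalence test).

**Optimisation.** Adam at learning rate 1e-3, batch size 32, no scheduler
and no early stopping; the reference recipe is 1000 epochs.  One seed
controls weight initialisation, shuffling, reparameterisation noise and
momentum draws, making the training log bit-reproducible per platform.

## Generation

Artificial patients are draws from the full generative model, not
conditional means:

1. **Latent draw (metric-walk, default).**  One random-walk step from a
   uniformly chosen metric centroid under its local geometry:
   `z ~ N(c_i, (M_i + lambda I)^{-1})`.  Since `M_i` is the local
   posterior precision, this is an exact draw from the encoder's
   aggregate posterior restricted to the centroid subsample — samples
   concentrate precisely where the latent manifold is supported, with the
   spread the metric prescribes.  A Hamiltonian walk on the volume
   density `sqrt(det G^{-1}(z))` was evaluated and rejected for
   generation: under diagonal-precision factors that density behaves like
   a kernel density of the centroids raised to the power `latent_dim / 2`,
   which collapses samples onto the centroid cloud's mode (measured
   latent sd 0.3–0.7 versus ~1.0 for the aggregate posterior, with
   visibly underdispersed decoded marginals).  A `prior-gaussian` sampler
   (`z ~ N(0, I)`) remains as an ablation baseline.
2. **Observation draw.**  `x ~ p(x|z)`: Gaussian noise with the learned
   `sigma_j` on numeric columns (clipped to `[0, 1]`), Bernoulli draws on
   binary columns, one categorical draw per one-hot block from the
   normalised decoder outputs.
3. **Inverse transform** back to a schema-valid patient record.

Generation is chunked (1,000 records at a time) with counter-based
per-chunk seeding: full chunks are always computed and the concatenation
truncated, so record *i* is identical for any requested size > *i*.

## Audit statistics

* **Numerical stability** — the fraction (as %) of numerical variables
  whose real-vs-artificial samples are *not* rejected by a two-sample
  Kolmogorov–Smirnov test at alpha = 0.05 (asymptotic p-values, no
  multiplicity correction; each variable is its own pass/fail).
* **Categorical stability** — the mean over binary + categorical
  variables of `100 x (1 - TVD)` between level-frequency vectors, TVD
  being half the L1 distance.
* **Correlation stability** — `100 x (1 - mean |Delta r|)` over
  off-diagonal entries of the numerical Pearson correlation matrices;
  constant columns contribute zero correlations with a warning.
* **Fidelity score** — the arithmetic mean of the three components,
  reported to one decimal (half away from zero).
* **Filter similarity** — the % of artificial records that are not exact
  duplicates of any real record on all decoded fields (an optional
  distance-threshold mode exists, off by default).
* **Degree of anonymization** — Euclidean nearest-neighbour distances in
  the min–max-scaled encoded space (so no wide-range numeric dominates):
  the median artificial-to-real NN distance over the median real
  leave-one-out NN distance; a ratio >= 1 flags the cohort anonymized.
* **Plausibility** — Cohen's kappa of each blinded rater against ground
  truth on a balanced categorization sheet, with a 95% CI from the
  Fleiss–Cohen–Everitt large-sample variance; kappa < 0.2 is interpreted
  as raters being unable to distinguish artificial from real records.
  Rater-vs-truth (not pairwise inter-rater) kappa is computed, since each
  rater judges real/artificial status against a known key.

### A calibration caveat on the numerical component

The KS pass-rate is intrinsically noisy: with 19 numerical variables
tested at alpha = 0.05, even a *perfect* generator loses about one
variable per audit on average (`P(at most 1 rejection) ~ 0.75`), and
because the real cohort is one fixed draw of n = 521 compared against a
much larger artificial sample, variables in which that draw is itself
atypical reject persistently.  Across 40 same-distribution resamples of
the synthetic cohort the numerical component averaged ~90 (range 79–100)
while the categorical and correlation components stayed above 96.  A
numerical stability below 100 therefore does not by itself indicate a
defective generator; the per-variable detail table should be read
alongside it.

## The synthetic study cohort

Because no real cohort ships with the package, a seeded fixture emulates
one: 521 patients, 85 features (19 numerics, 60 binaries, 6 four-level
categoricals; encoded width 103).  Records are driven by 4 standard-normal
latent factors per patient — broadly frailty/age, cardiometabolic burden,
respiratory burden, lifestyle — with correlation-scaled loadings (a
numeric with loading vector `w` keeps residual sd `sqrt(1 - ||w||^2)`, so
marginals stay unit-sd before the affine map to clinical units).  Binaries
use a logistic link with prevalence-calibrated intercepts (base rates
0.02–0.45); categoricals use softmax scores; BMI is derived exactly from
weight and height; numerics are rounded to clinical precision and clipped
to plausible ranges.  Haemoglobin and haematocrit share a 0.9 loading as a
deliberate near-duplicate measurement pair.

What the fixture does *not* emulate: missing data, measurement artefacts,
non-Gaussian marginal shapes (skewed labs, zero-inflation beyond range
clipping), longitudinal structure, and any claim of matching a real
population's prevalences or correlations.  Passing audits on the fixture
demonstrates that the pipeline preserves factor-driven mixed-type
structure at realistic noise levels — not that it would reproduce any
particular real cohort.  The fixture deliberately gives several numerics
mostly idiosyncratic variance (e.g. sodium ~96% residual), which is the
hard case for any latent-variable generator: marginal fidelity for those
columns rests entirely on the learned per-column noise scales.

## Problem sizes and defaults used in shipped analyses

The package's reference analysis trains on the 521 x 103 fixture for 300
epochs (the desk-scale version of the 1000-epoch recipe; quality saturates
slowly beyond that on this cohort), generates 5,000 artificial patients
(about 10 per real patient), and audits against the training cohort.  The
test suite uses smaller cohorts (120–200 patients) and shorter runs for
unit-level checks.

## Numerical choices and degenerate inputs

* Learned log-sigmas clamped to `[log 1e-3, log 1]`; posterior log-variance
  clamped to `[-8, 8]`; decoder probabilities clipped at 1e-6 in
  likelihoods.
* Fixed-point sub-steps of the implicit integrator iterate to 1e-13 (at
  most 20 iterations) in analysis code, 1e-10/5 inside training where the
  straight-through gradient makes extreme precision pointless.
* Degenerate numeric columns (observed min == max) encode as constant 0
  and are flagged; they decode to the stored constant.
* One-hot argmax ties break to the lowest-index level; binary threshold
  is exactly 0.5; integer rounding is half away from zero.
* An empty artificial cohort is rejected by every audit; leave-one-out
  distances require at least two real records; kappa requires at least 10
  items and non-degenerate marginals (p_e < 1).

## Known limitations

* The 85-feature schema is a stand-in: the real cohort the pipeline
  targets is not publicly deposited and its exact feature list is
  unknown.
* Conditional generation (fixing age, sex, ...) is out of scope.
* The straight-through gradient ignores the Jacobian of the Hamiltonian
  refinement; with few leapfrog steps the bias is small, but the
  refinement is best viewed as a stochastic perturbation aligned with the
  manifold rather than an exactly optimised component.
* No formal differential-privacy accounting: the confidentiality audit is
  empirical (duplicate counting and NN distances), not a worst-case
  guarantee.
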