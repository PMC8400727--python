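# Methods

## The model

`jdsnmf` fits a joint, multi-layer, semi-non-negative matrix factorization
to a collection of numeric matrices X_1, ..., X_I that share one axis —
either the samples (sample-matched multi-omics, e.g. several assays on the
same cohort) or the features (feature-matched, e.g. expression and
methylation matrices over the same genes measured in different cohorts).
After orientation the shared entities are always the rows, and the model is

    X_i  ≈  U · g(Z_i^1 · g(Z_i^2 · ... g(Z_i^N · H_i^N)))

* `U` (C × K_0) — the shared latent matrix over the matched axis,
  unconstrained in sign (the "semi" in semi-NMF: the data and the basis may
  be negative);
* `Z_i^n` (K_{n-1} × K_n) — per-block junction matrices linking consecutive
  layers, unconstrained in sign;
* `H_i^N` (K_N × M_i) — each block's deepest free latent, unconstrained;
* `g` — an elementwise activation (sigmoid by default, ReLU optional).
  Intermediate layer latents H_i^{n-1} = g(Z_i^n H_i^n) are *derived*, not
  free parameters, so their non-negativity (and, for the sigmoid, their
  confinement to (0,1)) holds by construction rather than by projection.

The training objective is

    L = Σ_i ‖X_i − U g(...)‖_F² + λ · Σ_S ‖S‖_F² ,   S ∈ {U, Z_i^n, H_i^N}

The penalty is implemented as a sum of *squared* Frobenius norms. The model
family's defining equation is ambiguous between ‖S‖_F and ‖S‖_F²; we chose
the squared form because the hyperparameter is described as an L2-norm
(weight-decay) parameter, and because it keeps the gradient smooth. This is
a documented interpretation, not a mathematical consequence.

Special cases: one block reduces the model to a deep semi-NMF; one block,
one junction layer and the identity activation reduce it to plain semi-NMF,
whose Frobenius optimum at bottleneck rank K is the rank-K truncated SVD
(Eckart–Young). That linear case is used throughout the tests as an exact
correctness oracle.

## Optimization

Gradients of L with respect to every free factor are closed-form
(backpropagation through the layered composition, derived by hand) and the
parameters are updated with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8; default
learning rate 1e-3). Training stops at `max_epochs` or when the best
objective has not improved by a relative `tol` (default 1e-5) for
`patience` (default 50) consecutive epochs; the best-objective snapshot is
restored. Early stopping monitors the *training* objective because the fit
is unsupervised — no labelled validation set exists inside `fit`; the
evaluation harness separately selects hyperparameters on validation AUC.
A non-finite objective raises an optimization error naming the epoch and
learning rate.

### Initialization

Initialization is deterministic. `U` takes the first K_0 left singular
vectors of the column-concatenation [X_1 | ... | X_I], scaled by the
singular values, with a fixed sign convention (largest-magnitude entry of
each left singular vector made positive). Each block's first-layer latent
starts from its slice of the right singular factor. Deeper layers are
initialized by recursive truncated SVD of the layer latent *weighted by the
current left-stack column norms*: factoring the plain (orthonormal) right
factor would be direction-degenerate — all its singular values are 1, so
truncation would drop an arbitrary direction — whereas the weighted
recursion composes, in the identity-activation case, to exactly the
truncated SVD of the input at the bottleneck rank. The inverse activation
is *not* applied before factoring (identity mapping); instead, after the
chain is built, `U` is refit by least squares against the *activated*
first-layer latent, which is the optimal `U` for the initialized chain
under any activation and leaves the identity case untouched.

`fit` runs Adam from both deterministic starts (with and without the
least-squares refit of `U`) and keeps the run with the lower final
objective. The two starts have complementary failure modes: the refit
start is far better on generic data but can stall on data generated from
the model itself, where its small initial residual starves the latent
factors of gradient; the raw-scale start behaves oppositely. Selection
uses only the training objective, and both starts coincide for the
identity activation (only one run is made).  `fit(..., n_restarts=k)`
additionally runs Adam from `k` perturbed copies of the raw start
(factor-scaled Gaussian jitter, seeded from the model seed) — a plain
multi-start guard against local minima, again selected by the final
training objective.

### Degenerate inputs

An all-constant block makes the SVD initialization meaningless and raises
an error; zero-variance *columns* are kept (no silent filtering) with a
block-level warning. Dimensions must satisfy K_0 < min(C, min_i M_i) and
decrease strictly across layers.

## Module construction

Each first-layer dimension k defines a module. A block's sample joins
module k when its value in row k of that block's first-layer latent exceeds
μ + 1.6449σ (upper 5% of a normal); a feature joins positively/negatively
when its value in column k of `U` passes μ ± 2.5758σ (1% two-sided). μ and
σ are computed per module — per latent row/column, σ with the population
formula (ddof = 0) — because the rule mirrors per-module z-scoring; a
`scope="global"` flag computes them over the whole matrix instead. Sample
thresholds are computed per block per module. Membership is not exclusive,
and empty modules are kept so a K_0-dimension model always yields K_0
modules. Note the rule's arithmetic: the thresholds include the candidate
itself in μ and σ, so very short rows (few entities) can be unable to
select symmetric outliers at all.

## Synthetic benchmarks

### Logistic multi-view benchmark

Each of three views draws an i.i.d. standard-normal predictor matrix
X ∈ R^{S×F} and an independent sparse coefficient vector β: by default 20
non-zero entries of magnitude 10 with uniformly random signs among F = 1000
features. Class probabilities follow a logistic model with additive noise,
y_s = expit(β₀ + x_s·β + ε_s), ε ~ N(0, 1.6) read as *variance* 1.6 (the
parameter is exposed as `noise_variance` to remove the σ-vs-σ² ambiguity);
β₀ defaults to 0 and hard labels threshold y_s at 0.5 (Bernoulli sampling
is available as an option). Samples are kept only when their hard labels
agree across all views — rejection sampling in batches, the simplest
construction that guarantees cross-view label consistency — until the
default 750/50/100 train/validation/test split fills. With three
independent views the acceptance rate is about 1/4; a rate below 1e-3
raises a design error.

What this emulates: small-sample, high-dimensional multi-view data where
only a sparse feature subset drives the phenotype and the views agree on
the label but not on the predictor structure. What it does not emulate:
correlated features, batch effects, non-Gaussian marginals, or shared
latent structure across views — so benchmark results here speak to the
factorizations' ability to retain label-relevant variance under strong
compression, not to any biological realism.

### Generative recovery

`simulate_from_model` draws all factors from N(0,1), composes
X_i = U g(...) and adds Gaussian noise, returning the ground truth. Since
the true model lies in the fitted family, reconstruction RMSE near the
noise floor is a direct check of optimizer and parameterization together.

## Evaluation protocol

Latent features (rows of `U` for sample-matched data; a chosen layer's
latent transposed for feature-matched data) are scored by fixed, untuned
classifiers: a linear SVM, a 500-tree random forest (scaled down from a
much larger forest for runtime; impurity importances are insensitive to
this at these problem sizes), and a three-hidden-layer MLP with L2 and
early stopping. AUC is the area under the ROC curve; multiclass problems
use one-vs-rest macro averaging. The benchmark harness fits each
factorization once per dataset on all samples (the factorization is
unsupervised and sees no labels — a transductive protocol standard for
feature extraction), trains classifiers on the training split, selects
hyperparameters by validation AUC only, and reports test AUC. Paired AUC
vectors are compared with the two-sided Wilcoxon signed-rank test; a
univariate t-filter is included as a generic feature-selection baseline
for synthetic data (it stands in for moderated differential-expression
filters that only make sense on real microarray data).

## Interpretation

* **Local-surrogate importance** perturbs each instance with Gaussian
  noise scaled per feature, weights perturbations by
  exp(−d²/kernel_width²) on standardized distance (default kernel width
  0.75·√d), fits a ridge surrogate (α = 1) to the classifier's
  positive-class probability, and sums absolute surrogate coefficients
  over instances. 1000 perturbations per instance by default; all defaults
  configurable, all draws seeded. A constant predictor yields zero weights
  with a warning.
* **Random-forest importance** reports normalized impurity importances.
* **Age regression** fits, per module, OLS of the module's sample latent
  value on intercept + age + sex + diagnosis + the principal components of
  the latent matrix that are *not* related to age. "Not related" is
  operationalized as a Pearson correlation test with age at p ≥ 0.05
  (configurable), over at most the top 10 PCs so the design stays
  well-conditioned. Constant covariates are dropped with a warning; the
  age coefficient's sign carries the direction of association. Raw
  p-values are reported; Benjamini–Hochberg correction is available via
  statsmodels if desired.
* **Gene-set overlap** is a two-sided Fisher exact test on the 2×2 table
  of module membership against a reference set within a declared universe.

## Problem sizes and numerical choices

The packaged analyses use deliberately small instances so every check runs
on a single CPU in minutes: the linear-oracle check fits twenty 50×40
matrices at bottleneck rank 5 (ratio to the truncated-SVD residual ≤ 1.05);
generative recovery fits twenty 40×30 single-block models at dims (5, 4),
noise sd 0.01, with a 60 000-epoch Adam budget (learning rate 0.05,
patience 8000) and two perturbed restarts — the long budget and the
multi-start are convergence requirements of the tight 2σ recovery target,
and the rare run that still ends in a local minimum is absorbed by the
success-rate criterion (≥ 18/20); the multi-view
benchmark runs five replicates at S = 300, F = 200 per view with the study
noise and sparsity settings. Tie-breaks and sign conventions in the SVD
are fixed deterministically; denominators in multiplicative NMF updates
carry an ε-guard of 1e-10; all generators take explicit seeds and repeat
bit-identically.

## Known limitations

* No out-of-sample `transform` for the joint factorization: like spectral
  embeddings the decomposition is transductive. New samples require
  refitting (the NMF baseline does support projection of new rows).
* The optimizer is first-order; very deep configurations (N > 4) or
  ill-scaled inputs may need smaller learning rates. Divergence raises
  rather than returning a bad model.
* The local-surrogate explanation assumes locally smooth classifier
  probabilities; tree ensembles with hard steps yield noisier weights.
* Real multi-omics preprocessing (batch correction, probe mapping,
  methylation β-value handling) is out of scope; inputs are generic
  numeric matrices.
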