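# Methods

## Data model and notation

Each subject `i` contributes a feature vector `x_i ∈ R^dx` (standardized
column-wise at load time; zero-variance columns map to zeros with a warning)
and a phenotype vector `y_i ∈ R^dy` with `d_y` typically between 6 and 15.
Feature columns carry modality-block tags (`eeg_psd:...`, `imaging:...`);
the library treats blocks as annotations — modality-specific feature
extraction (convolutional EEG/MRI backbones, text encoders) is out of scope,
and inputs are assumed to be precomputed per-modality features. Phenotype
dependencies are a weighted undirected graph over the `d_y` dimensions,
stored as a `d_y × d_y` adjacency with zero diagonal.

## Encoder and latent space

The encoder is a fully connected trunk (default widths 512/256/128, GELU,
batch normalization, dropout 0.3 after the second and third layers) with two
linear heads for `μ` and `log σ²` (latent dimension 64 by default; small
widths are used throughout the tests, where the published defaults would be
badly over-parameterized for simulated cohorts). `log σ²` is clamped to
[−20, 20]. Batch normalization uses batch statistics during training and
running statistics (EMA momentum 0.9, refreshed by an untraced pass over the
training split) at evaluation, so eval-mode predictions are deterministic.

Latent regularizers:

- KL to the isotropic Gaussian prior (closed form, batch-averaged).
- A variance-plus-proximity term `Σ_j Var(z_·j) + β·mean‖z_i − z_i^prior‖²`
  with `z^prior` a fresh seeded N(0, I) draw per batch. The printed form of
  this objective *penalizes* latent variance although its stated intent is
  diversity; the formula is implemented as printed with a `variance_sign`
  switch for the other reading. Variance is the unbiased batch variance
  (batch of 1 → 0 with a warning); whether it should be dataset-wise is
  unspecified, batch-wise is used.
- A mutual-information term implemented as the variational bound
  `E_q[log p(x|z)] − E_q[log q(z|x)]` with S = 1 reparameterized sample and a
  unit-variance Gaussian observation model; neural MI estimators are out of
  scope. Defaults β = 1, λ_mutual = 0.1 are package choices.

## Graph decoder

Decoding solves `y = W_d z + A y`. Two solvers are provided and must agree:
`closed_form` computes `(I − A)⁻¹ W_d z` by linear solve; `unrolled` runs
fixed-point message passing `y^(k+1) = W_d z + A y^(k)` (default 8 steps).
The truncation error of `K` unrolled steps is `O(ρ^{K+1}/(1 − ρ))` in the
spectral radius ρ, which dictates where the two solvers can be expected to
agree tightly: at ρ = 0.7 fifty steps are below 1e−6, at ρ = 0.9 the error
is ≈ 5e−2 regardless of tolerance wishes. `project_adjacency` symmetrizes,
zeroes the diagonal, and rescales so ρ ≤ 1 − δ (δ = 0.05 default); the model
itself never constrains the adjacency magnitude, but the fixed point is
ill-posed without it. The pre-layer of the decoder is kept linear so that
decoding is exactly linear in `z` when the residual block is disabled; the
two-layer GELU residual block (`R(y) + y`, output layer zero-initialized so
refinement starts at the identity) adds the nonlinear part. The "graph
attention" of the architecture table has no defining equations and is
realized as the weighted message passing above, with the learned edge
weights playing the attention role.

A learnable adjacency is parameterized by its strict upper triangle
(symmetric by construction, so the symmetry penalty `‖A − Aᵀ‖²_F` is
identically zero yet still computed and logged), rescaled differentiably
through an eigendecomposition, L1-penalized, and hard-thresholded at 1e−3
only at export.

### Identifiability and the structural likelihood

Under the mean-squared decoding loss the adjacency is not identifiable: for
any admissible `A`, the pair `(A, (I − A)B)` produces the same predictions
as `(0, B)`, and the L1 penalty then drives `A → 0`. Identification requires
conditioning on the observed phenotypes: with node noise entering the fixed
point (`y = W_d z + A y + e`), the exact Gaussian likelihood is

    ½‖(I − A)y − W_d z‖²/σ² + (d_y/2) log σ² − log|det(I − A)|

per subject. The log-determinant Jacobian term is what prevents the
degenerate self-representation `(I − A)y ≈ 0`. `recover_adjacency` minimizes
this jointly with the decoding MSE and the adjacency L1 (weight 0.02) by
full-batch Adam (lr 0.02, 1500 steps default; 800 suffice on the default
scenario), with a linear deterministic encoder to `k` latent dimensions.
Support recovery is scored by ranking `|Â|` against the generating support
(AUROC), which is invariant to the latent rotation ambiguity: only
`span(W*)` and the support of `A*`, not `W*` itself, are recoverable.

## Hierarchical attention

Three abstraction levels (1 sensorimotor, 2 cognitive control, 3 executive)
partition the phenotype columns. Each level projects `z` through
`h_l = f(W_l z + b_l)` (GELU default, width 32), predicts its own columns
with a linear head (zero-filled to full `d_y`), and the final prediction is
`ŷ = Σ_l α_l y^(l)` with `α = softmax_l(u_lᵀ h_l)`. By default the
compatibility scores are batch-averaged before the softmax (one weight per
level, as the weights are written per-level, not per-subject); a per-subject
variant is configurable. The attention-sparsity term `Σ_l |α_l|` is computed
literally and equals 1 for softmax weights, so its multiplier has no
gradient effect; this is kept as stated rather than reinterpreted, and an
optional entropy penalty (`attention_entropy` weight) provides effective
concentration pressure for users who want it. Whether per-level predictions
come from level-specific decoders or a shared one is an open design point;
level-specific linear heads on `h_l` are used.

## Multi-task and uncertainty objectives

Tasks default to the hierarchy levels (any column partition is accepted).
Adaptive weights follow `λ_t = 1/(EMA[‖∇L_t‖²] + ε)` rescaled to sum to the
number of tasks; the gradient statistic is taken on the shared parameters
per epoch and EMA-smoothed (β = 0.9). As printed, larger gradients yield
*smaller* weights, the opposite of the surrounding prose about emphasizing
hard tasks; the formula wins and the property tests assert the printed
relation. Parent–child consistency compares a parent's prediction with
fixed column-group means of its child's columns (contiguous, nearly equal
groups — the subtraction is otherwise dimensionally undefined). The
heteroscedastic loss is `Σ_t ½σ_t⁻²‖y_t − ŷ_t‖² + ½ log σ_t²` with
learnable clamped `log σ_t²`; its stated "ground truth" symbol is treated
as the target, matching the convention of every other objective. The
multi-level evidence-bound objective is subsumed by this task
decomposition rather than duplicated.

## Self-supervised pretraining

A mirrored decoder (widths reversed) reconstructs the input from the
posterior mean; auxiliary priors default to a single standard normal (the
number of priors J is undefined in the source setting; J = 1 is a package
choice with a hook for user-supplied per-dimension Gaussians); the
contrastive term is InfoNCE with cosine similarity, temperature τ = 0.1
default, positives from augmented views (jitter 0.05·SD, feature masking
p = 0.1, subject scaling U(0.9, 1.1); all seeded) and in-batch negatives.

## Synthetic cohorts

The generator mirrors the decoder's structural equation:
`z* ~ N(0, I_k)`, `y = (I − A*)⁻¹(W* z* + ε_y)`, features from two linear
modality blocks (`eeg_psd` 60% of columns, `imaging` the rest) plus
independent noise. Placing `ε_y` inside the propagation gives the phenotype
covariance the sandwich form `(I − A*)⁻¹(W*W*ᵀ + σ_y²I)(I − A*)⁻ᵀ` and is
the choice that makes adjacency recovery well-posed. Defaults: n = 800,
d_x = 40, d_y = 10, k = 5, edge density 0.2 (exact edge count, weights
±U(0.4, 0.8), spectral radius capped at 0.8), σ_y = 0.3 and σ_x = 0.1 —
about ten percent noise variance against unit-scale signal, a realistic
phenotype-measurement noise level. What the generator does *not* emulate:
raw EEG waveforms, imaging forward models, nonlinear feature mixing,
missing data, and site/batch effects — passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Training, evaluation, statistics

Supervised training uses Adam (lr 0.001, batch 32), at most 100 epochs,
early stopping on validation loss with patience 10, everything seeded; any
non-finite loss aborts naming the first offending component, and every
logged total equals the sum of its logged weighted components. Splits use
largest-remainder 70/15/15 apportionment (ties resolved train, val, test),
optionally stratified on a binary column. Continuous columns are scored by
MAE/RMSE; binary columns by accuracy/precision/recall/F1 (macro) and AUROC
from the raw scores (classes at 0.5; single-class AUROC reported missing
with a warning). The power utility inverts the noncentral-t power function
of the two-tailed paired t test by integer bisection. The `compare`
protocol runs Shapiro–Wilk on paired differences and Levene across runs,
then a paired t test (or Wilcoxon signed-rank when normality fails) per
metric with Holm–Bonferroni correction.

Problem sizes in the test suite and acceptance script (cohorts of 200–800
subjects, encoder widths 5–32, 30–200 epochs, recovery over seeds 1–5) were
chosen as the smallest instances on which every property is informative.

## Known limitations

- Teacher-forced decoding (using observed `y` on the right-hand side at
  training time) is implemented only inside the structural likelihood, not
  as a general decoding mode.
- The attention-sparsity multiplier is inert under softmax weights by
  construction (see above).
- Learned adjacencies are undirected; directed decoding is out of scope.
- Gradient-adaptive task weighting is computed per epoch, not per step, to
  keep the extra gradient passes cheap.
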