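# lcen — latent cognitive embedding networks

`lcen` models multi-dimensional cognitive phenotypes (reaction time, working
memory span, planning scores, ...) from tabular multimodal features
(EEG power-spectral densities, imaging-derived measures) with a structured
latent-variable network, and ships a seeded synthetic-cohort generator so
every part of the model can be validated by parameter recovery against known
ground truth. It is aimed at researchers who want an interpretable
encoder–decoder phenotype model with an explicit, learnable dependency graph
over the phenotype dimensions rather than a black-box regressor.

## Model

A variational encoder maps subject features `x ∈ R^dx` to a diagonal-Gaussian
posterior `q(z|x) = N(μ, diag σ²)` over latent cognitive factors
`z ∈ R^dz`, sampled with the reparameterization trick `z = μ + σ ⊙ ε`.
Phenotypes are decoded through the implicit graph system

    y = W_d z + A y   ⇒   y = (I − A)⁻¹ W_d z,

where `A` is a sparse symmetric adjacency over phenotype dimensions whose
spectral radius is kept below `1 − δ` so the fixed point is well-posed. `A`
may be fixed from a known dependency graph or learned (symmetric by
construction from its upper triangle, L1-penalized). Because any pair
`(A, (I − A)B)` predicts identically under a plain squared-error loss, the
package also scores the structural equation itself,

    ½‖(I − A) y − W_d z‖²/σ² + (d_y/2) log σ² − log|det(I − A)|,

the exact Gaussian likelihood when node noise enters the fixed point — this
is what makes the adjacency identifiable and is the objective behind
`lcen.recover_adjacency`.

On top of the decoder, a three-level hierarchical attention head (sensorimotor /
cognitive-control / executive tiers) projects `z` per level, scores each
projection against a learnable context vector, and combines the per-level
predictions with softmax weights `α = softmax(uᵀh)`. Training couples the
reconstruction objective with the variational KL, latent variance/proximity
and disentanglement (squared off-diagonal covariance) penalties, graph
smoothness `Σ_(k,l)∈E |A_kl|‖ŷ^(k) − ŷ^(l)‖²`, gradient-norm adaptive
multi-task weights `λ_t = 1/(E‖∇L_t‖² + ε)`, parent–child hierarchy
consistency, and a heteroscedastic uncertainty loss with learnable per-task
variances. A contrastive self-supervised phase (input reconstruction +
auxiliary-prior KL + InfoNCE over augmented views) can initialize the encoder.

Everything runs on numpy with `autograd` for exact reverse-mode gradients;
no GPU or deep-learning framework is required.

## Worked example

Simulate a cohort with known ground truth, train, and inspect the metrics:

```bash
lcen simulate --n 200 --seed 7 --out-dir demo
lcen train --features demo/features.tsv --phenotypes demo/phenotypes.tsv \
    --graph demo/graph.tsv --config demo_cfg.yaml --seed 1 --out-dir run
lcen power -d 0.5
lcen split --n 3000
```

with `demo_cfg.yaml`:

```yaml
model:
  encoder: {layer_widths: [32, 16], dropout_rate: 0.1, dropout_after: [1], batch_norm: false}
  decoder: {hidden_widths: [16, 32]}
  hierarchy:
    level_dims: {1: [0, 1, 2, 3], 2: [4, 5, 6], 3: [7, 8, 9]}
    task_edges: [[3, 2], [2, 1]]
  lambdas: {kl: 0.01, graph: 0.001}
  max_epochs: 30
```

This prints (abridged):

```
{"mae": 0.791, "rmse": 0.987, "rmse_pooled": 1.007}   # run/metrics.json aggregate
 epoch  train_total  val_total  alpha_1  alpha_2  alpha_3
    29       22.200     18.393    0.351    0.310    0.339
{"min_n": 34}
{"train": 2100, "val": 450, "test": 450}
```

The aggregate MAE/RMSE are per-phenotype-column means on the held-out test
split of this small noisy cohort; `alpha_*` are the hierarchical attention
weights logged per epoch (they always sum to 1). `min_n = 34` is the smallest
sample size at which a two-tailed paired t test with medium effect size
d = 0.5 and α = 0.05 reaches 80% power, and the split counts show the
largest-remainder 70/15/15 apportionment of 3000 samples.

Parameter recovery from the library:

```python
import lcen
features, phenotypes, graph, truth = lcen.simulate_cohort(seed=1)
A_hat, params, cfg = lcen.recover_adjacency(features, phenotypes, k=5, seed=1)
print(lcen.support_auroc(A_hat, truth.A_true))  # 1.0
```

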