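# modsig

**Multiplicative modulatory processes for mutational-signature analysis.**

Somatic mutation catalogues of cancer genomes are conventionally explained
by an *additive* model: the expected count of mutation type *j* in sample
*k* is a non-negative mixture of signature profiles,

```
X̃ᵏⱼ = Σᵢ aᵏᵢ μⁱⱼ ,
```

where each signature μⁱ is a probability distribution over the 96
trinucleotide-context single-base-substitution (SBS) channels and aᵏᵢ ≥ 0
is its activity (exposure) in sample *k*.  Additive mixtures can only add
mutations, yet fitted catalogues show *systematic* residual structure —
whole base-substitution classes over- or under-predicted in a coordinated,
cancer-type-specific way, as expected if DNA-repair-like processes
selectively **remove** mutations of some types and spare others.

`modsig` extends the additive model with one global, multiplicatively
acting *modulatory process*: a 96-channel profile *r* with per-sample
activities cᵏ ≥ 0 that rescales the additive reconstruction,

```
Xᵏⱼ ~ Poisson( (1 + cᵏ rⱼ) · X̃ᵏⱼ ),     1 + cᵏ rⱼ ≥ 0 .
```

Channels with rⱼ > 0 are amplified, channels with rⱼ < 0 depleted, and
cᵏ = 0 recovers the plain additive (NMF/KL) model, so the extension is
nested.  Only the product c·r is identified; the scale degeneracy is fixed
by the gauge max|r| = 1.  The package provides

- **catalogs** — COSMIC-style TSV I/O for 96-channel catalogues,
  signature sets and activity matrices (both orientations, canonical
  channel ordering, pseudo-counts);
- **residuals** — additive (X − X̃) and multiplicative (X/X̃, with
  pseudo-count 1) residual profiles, a Poisson-resampling null control,
  sample clustering by residual correlation (complete linkage on
  1 − correlation, threshold 0.75) and entropy ranking of clusters by
  cancer-type composition;
- **model / inference** — the Poisson log-likelihood, its analytic
  gradients in a, r and c, gauge fixing, and an alternating
  maximum-likelihood fit (bound-constrained quasi-Newton with analytic
  gradients, random restarts, three alternations by default);
- **simulate** — a synthetic-data generator and recovery benchmark
  (50 datasets × 100 samples by default) with known injected processes;
- **evaluation** — cosine similarity, MSE, per-channel modulation impact
  ⟨1 + cᵏ rⱼ⟩ₖ, log-likelihood gain, BIC comparison and per-cancer-type
  report tables;
- a `modsig` CLI (`simulate`, `fit`, `residuals`, `cluster`, `evaluate`)
  wrapping the library.

## Worked example

Simulate one cancer-type-like dataset (100 samples, 10 signatures of
which 4 are active per sample, one hidden modulatory process), then infer
the process back by alternating maximum likelihood:

```python
import numpy as np

from modsig import (
    SimulationConfig, sample_signature_pool, simulate_dataset,
    alternating_fit, cosine_similarity, impact_profile, model_comparison,
)
from modsig.inference import FitConfig

config = SimulationConfig(n_samples=100, seed=42)
rng = np.random.default_rng(42)
pool = sample_signature_pool(config, rng=rng)
dataset = simulate_dataset(config, pool, rng=rng)

result = alternating_fit(dataset.catalog, dataset.signatures, FitConfig(seed=0))

print(f"additive log-likelihood : {result.additive_log_likelihood:.1f}")
print(f"extended log-likelihood : {result.log_likelihood:.1f}")
print(f"log-likelihood gain     : {result.gain:.1f}")
print(f"delta BIC (extended - additive): "
      f"{model_comparison(result, n_samples=100).delta_bic:.1f}")
print(f"cosine(r_hat, r_true)   : "
      f"{cosine_similarity(result.modulatory.r, dataset.true_modulatory.r):.3f}")
print(f"impact range            : "
      f"{impact_profile(result.modulatory).min():.2f} .. "
      f"{impact_profile(result.modulatory).max():.2f}")
```

Output:

```
additive log-likelihood : 284444.2
extended log-likelihood : 286089.1
log-likelihood gain     : 1644.9
delta BIC (extended - additive): 1492.6
cosine(r_hat, r_true)   : 0.970
impact range            : 0.58 .. 1.50
```

The gain of ~1.6 × 10³ log-likelihood units for 96 + 100 extra parameters
gives a decisively positive ΔBIC: the data carry strong evidence for the
modulatory process.  The recovered profile matches the injected one at
cosine 0.97, and the impact profile shows channels depleted to 0.58× and
amplified to 1.50× of their additive expectation.

The same fit on real data, given a catalogue and a signature set:

```sh
modsig fit --catalog catalog.tsv --signatures signatures.tsv \
           --by-group cancer_types.tsv --seed 7 --out fit/
```

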