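# metricvae

A sequence variational autoencoder for molecules whose training objective
adds a **log-ratio metric-learning loss** with latent-proximity-constrained
triplet sampling, so that molecular structure *and* a chosen continuous
physical property are embedded locally and continuously in the latent
space. The package also implements the standard **joint-regression VAE**
baseline and a **neighbor-point regression protocol** for quantifying how
smoothly properties vary over an embedding.

## Who this is for

Anyone building continuous "chemical spaces" for molecular design:
latent-space optimization, property-guided generation, or transfer of an
embedding to new descriptors. The core problem it addresses: a plain VAE
embeds structure but not properties; a VAE trained jointly with a property
regressor tends to compress the property into one or two linear latent
axes, so neighboring points stop being structurally similar and *other*
properties drift. The metric objective instead matches **ratios of
distances** so no single axis can absorb the property.

## The model

A token-sequence VAE (bidirectional GRU encoder → diagonal Gaussian
posterior q(z|x), z ∈ ℝᴰ; autoregressive GRU decoder) trained with a
total-correlation-decomposed KL term:

    L = L_recon + α₁·I(z;n) + α₂·TC(z) + α₃·KL_dims + γ·L_metric

where the KL decomposition (mutual information, total correlation,
dimension-wise KL) is estimated per minibatch by stratified importance
weighting, α₂ anneals 1.25 → 0.75 by 0.1 per epoch, and the metric term is

    L_metric = mean over triplets ( log D(f_a,f_n)/D(f_a,f_p)
                                  − log D(y_a,y_n)/D(y_a,y_p) )²

with D squared Euclidean distance, f the encoder embedding, y the target
property, and (a, p, n) anchor/positive/negative triplets drawn only from
each anchor's nearest 25% of the batch in latent space. The adaptive
weight γ = 0.1·(1 − maxᵢ |corr(zᵢ, y)|) vanishes whenever the property is
already linearly captured by one latent axis, preventing collapse onto a
single dimension. Ratio matching makes the loss invariant to the scale of
both the property and the latent space.

Embeddings are scored with a local protocol: for each held-out center
molecule, fit a linear (ridge) regression on its k = 10 nearest training
embeddings and measure the MAE of predicting the center's properties —
including properties never used in training.

## Worked example

```python
from metricvae import compare_embeddings
from metricvae.experiment import scaled_run_config
from metricvae.synthetic import SyntheticSpec, generate_encoded_dataset
from metricvae.training import neighbor_evaluation, train

sequences, props, vocab = generate_encoded_dataset(
    SyntheticSpec(n_molecules=800, alphabet_size=8, seed=2))

reports = {}
for mode in ("vae", "metric"):
    result = train(scaled_run_config(mode, seed=2, epochs=8), sequences, props, vocab)
    reports[mode] = neighbor_evaluation(result, k=10, n_centers=80)
    print(f"{mode:>6}: " + "  ".join(f"{k} MAE {v:.3f}" for k, v in reports[mode].mae.items()))
print(compare_embeddings(reports["metric"], reports["vae"])["a_wins"], "wins")
```

prints

```
   vae: target MAE 2.548  other MAE 2.534
metric: target MAE 2.404  other MAE 2.390
2 wins
```

i.e. after eight epochs the metric-trained embedding already predicts the
training label ("target") better from 10 latent neighbors, and the
correlated, *untrained* property ("other") improves alongside rather than
degrading. Longer training (see the experiment module's defaults) widens
the gap substantially. The `examples/` directory has one narrative script
per capability: benchmark generation, training with loss-component logs,
and embedding comparison; the same operations are available from a thin
CLI (`metricvae synth|train|evaluate|compare`).

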