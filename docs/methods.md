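# Methods

## Model

Molecules enter as token sequences: character-tokenized SMILES (a fixed
digraph list keeps `Cl`, `Br`, `Si`, `Se` whole) or pre-tokenized
whitespace-separated files such as grammar production-rule sequences.
Each sequence is wrapped in START/END markers and padded to a fixed
width.

The backbone is a recurrent VAE. The encoder is a multi-layer
bidirectional GRU; the final states of the top layer (both directions,
concatenated) pass through one linear map to the mean μ and log-variance
of a diagonal Gaussian posterior over z. The decoder is a unidirectional
GRU of the same depth whose per-layer initial state is a learned tanh map
of z; z is also concatenated to every decoder input embedding so the
conditioning does not have to survive the recurrence. Training uses
teacher forcing; reconstruction checks use greedy argmax rollout.
Reference architecture defaults: 3 layers, 384 hidden units, 900-dim
token embedding, 50-dim latent, Adam at learning rate 0.001.

All forward functions are written over a flat dict of numpy arrays and
differentiated with `autograd`; the optimizer is a hand-rolled Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with global gradient-norm clipping at
5.0 to stabilize recurrent training.

## Objectives

**Reconstruction.** The trainer uses the per-molecule summed sequence
cross-entropy (averaged over the batch), which keeps the term on the same
per-molecule scale as the KL terms; a per-token mean variant is exported
for diagnostics (its value on uniform logits is ln V).

**KL decomposition.** Instead of one KL-to-prior term, the objective
weights three components estimated per minibatch: index-code mutual
information, total correlation, and dimension-wise KL. Aggregate
densities q(z) and q(z_j) are estimated by minibatch stratified sampling:
for a batch of M from a dataset of N, each element's mixture weight on
its own posterior is 1/N, one designated off-diagonal slot (cyclically
the next element) carries (N−M+1)/(N(M−1)), and the remaining slots get
1/(M−1); rows of the weight matrix sum to one. The three estimates
telescope, so their sum equals the plain minibatch KL estimate exactly —
a useful internal consistency check. Weights: α₁ = α₃ = 0.75 fixed;
α₂ anneals from 1.25 to 0.75 by 0.1 per epoch (counted from epoch 0), a
high early total-correlation weight encouraging independent latent
dimensions before the metric term shapes them.

**Log-ratio metric term.** For triplets (a, p, n) the loss penalizes the
squared difference between the log ratio of squared Euclidean latent
distances and the log ratio of squared property distances. An
ε = 1e-8 guard inside every distance keeps the logs finite for duplicate
molecules. Matching *ratios* makes the term invariant to rescaling either
the property or the latent space, so any continuous label works without
normalization.

**Triplet sampling.** Every batch element serves once as anchor. The
other members are ranked by Euclidean distance to the anchor; the nearest
⌈0.25·(batch−1)⌉ (minimum 2) are kept; the kept members are re-ranked by
|y − y_a| (ties broken by batch index); consecutive non-overlapping pairs
of that ranking become (positive, negative), the property-nearer member
as positive, with an incomplete last pair dropped. Structurally distant
molecules therefore never act as metric targets. The pairing rule
("pairs in ranking order") covers the whole neighborhood once per anchor
at linear cost; the selection is discrete and is computed on detached
values.

**Adaptive weight γ.** γ = c·(1 − maxᵢ |Pearson(zᵢ, y)|) with c = 0.1,
recomputed on every minibatch. If one latent dimension already encodes
the property linearly, the metric pressure vanishes — the safeguard
against embedding the property in a single axis. Degenerate batches
(zero variance in y or a latent dimension) contribute correlation 0.
γ is a loss *weight*, not a gradient path: it is computed from detached
values.

**Where the metric term acts.** The log-ratio loss, the triplet ranking,
and γ all operate on the posterior mean μ — the deterministic embedding
f(x) that neighbor search and evaluation use — rather than on the sampled
z. Early in training the posterior variance is near 1 while the spread of
μ across molecules is orders of magnitude smaller, so a metric loss on
the sampled z sees mostly reparameterization noise and cannot organize
the embedding; on μ it acts directly on the quantity being scored. The
reconstruction and KL terms still flow through the sampled z, so the
generative model remains a proper VAE.

**Joint baseline.** A 2-layer perceptron head (affine–tanh–affine,
hidden width 64) predicts y from the sampled z; its mean squared error
enters the total with a fixed weight 0.1. A strictly linear 2-layer
stack would collapse to one layer, so "2-layer regression" is read as a
small MLP. With head weight 0 (and likewise metric coefficient 0) the
joint and metric modes reduce bitwise to plain VAE training — the head's
parameters come from their own RNG stream, so adding it never perturbs
backbone initialization.

## Evaluation protocol

For each held-out center molecule: embed everything with the posterior
mean; find the k = 10 nearest training embeddings (Euclidean); fit a
per-property local linear model on those k points by centered ridge
regression ((XcᵀXc + λI)w = Xcᵀyc, intercept unpenalized, default
λ = 1e-3); predict the center; report the mean absolute error over
centers, per property. With latent dimension ≥ k the local fit is
underdetermined and ridge supplies the minimum-norm resolution; at k = 1
the fit degenerates to nearest-neighbor regression by construction.
Centers are sampled without replacement from a dedicated validation
split; the splitter reserves train/validation/test = 80/10/10 when
evaluation is enabled and 80/20 otherwise. At full scale the protocol
uses 1,000 centers; the scaled experiment uses 200.

Model-vs-model comparison counts, per property, which report has the
strictly smaller MAE (ties to neither) and reports the win fraction.

## Synthetic benchmark

The generator emulates the one assumption the metric objective needs:
structure–property consistency. Sequences are uniformly random tokens
(alphabet size 8, lengths 4–12 by default); the target property is
y = w·c(s) + a·tanh(w·c(s)) + ε with c(s) the token-count vector,
w per-token weights (drawn N(0,1) from the spec seed unless given),
a = 1 the nonlinearity scale, and ε ~ N(0, 0.1²) — noise small relative
to the property spread (sd ≈ 2–3) so composition genuinely determines
the property. A second property, y plus independent N(0, 0.1²) noise,
stands in for a correlated descriptor not used in training. The property
is permutation-invariant in token order, so "similar structure ⇒ similar
property" holds by construction.

What the benchmark does *not* emulate: chemical grammar (sequences have
no syntax), the heavy-tailed and multimodal distributions of real
quantum-chemical properties, order-sensitive properties, and duplicate
or near-duplicate molecules. Passing the synthetic comparison shows the
machinery works in the regime the method assumes; it does not quantify
gains on real chemistry.

## Scaled experiment sizes

The replicated comparison trains on 2,000 molecules (1,600 train / 200
validation / 200 test) for 20 epochs at batch 64 with a deliberately
small backbone — 1-layer bidirectional GRU, 32 hidden units, 16-dim
embedding, 8-dim latent — and scores 200 centers with k = 10. One
replicate (both models) takes about 70 s on one CPU core; the acceptance
script runs ten replicates. The reference-scale defaults remain in
`ModelConfig` for full-size runs.

## Numerical choices

- Glorot-uniform weight init, zero biases, N(0, 0.1) token embeddings.
- Sequence masking: padded steps never update GRU states, so the final
  forward state is the state at each sequence's last valid token.
- Per-epoch α₂ decay (the schedule is stated per epoch, not per step).
- One run seed drives everything through fixed offsets: split, parameter
  init, head init, epoch shuffling + reparameterization noise, center
  sampling. Same seed ⇒ bitwise-identical trajectory on one device.
- Non-finite losses abort training immediately with the epoch/batch in
  the message.
- Checkpoints are single `.npz` files embedding the config and
  vocabulary as JSON metadata.

## Known limitations

- Desk-scale only: single process, single device; no grammar-constrained
  decoding, no Bayesian-optimization structure search.
- The 25% triplet neighborhood is computed per batch, so its absolute
  radius shrinks as batches get smaller.
- The MSS aggregate-density estimate is biased at small batch sizes; the
  decomposition's *split* between MI/TC/dimension-wise KL should be read
  qualitatively at batch 64, even though the sum is exact.
- Greedy decoding only; reconstruction accuracy is a lower bound on what
  beam search would report.
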