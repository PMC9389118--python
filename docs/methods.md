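# Methods

## Model

`cmipred` predicts circRNA–miRNA interactions purely from the topology of
the known interaction network. The network is a bipartite graph: n circRNAs,
m miRNAs, edges = catalogued interactions. Each node owns a trainable
D-dimensional embedding; K propagation layers refine the embeddings by
aggregating, for every node, (a) a self-message W₁ᵏe (undecayed, which
preserves the node's own signal as depth grows), (b) the transformed
embeddings of its neighbours, and (c) an elementwise neighbour–self
interaction term W₂ᵏ(e_v ⊙ e_u) that passes more signal between nodes with
aligned embeddings. Neighbour messages decay by the graph-Laplacian factor
1/√(|N(u)||N(v)|), so messages through hub nodes are damped. The activation
is LeakyReLU. Per-layer embeddings are concatenated (not summed), so the
pair score ⟨e_u\*, e_v\*⟩ decomposes into per-hop inner products and no
single depth has to carry all the signal.

Key modelling assumptions:

- Interactions are missing-not-observed: an absent pair is *unlabeled*, not
  negative. Training therefore uses the pairwise BPR objective (rank known
  partners above sampled unlabeled ones) rather than a pointwise loss, and
  evaluation samples balanced "negatives" from the unlabeled pairs.
- Association topology is informative on its own; no sequence, expression
  or similarity side-information enters the model.
- Embeddings are stored as matrix rows; transforms act by right
  multiplication. This is the column-vector formulation transposed, with
  identical expressiveness.

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| K (layers) | 2 | hops of interaction context absorbed; best CV setting on the real benchmark, deeper stacks over-smooth |
| D (embedding size) | 256 | per-layer width, transformation size d_k = D at every layer; a single D keeps the sweep identifiable |
| LeakyReLU slope | 0.2 | the convention of the collaborative-filtering architecture this follows |
| message / node dropout | 0.1 / 0.1 | training-only regularisation; message dropout zeroes aggregated messages elementwise, node dropout removes a node's outgoing messages for a whole forward pass |
| lr | 1e-3 | Adam step size (β₁=0.9, β₂=0.999, ε=1e-8) |
| batch size | 1024 | BPR triples per Adam step |
| λ (L2) | 1e-5 | covers E⁰ and all W₁ᵏ, W₂ᵏ |
| max epochs / patience | 400 / 20 | early stopping on validation AUC |
| val fraction | 0.1 | slice of *training* positives held out to drive early stopping; test folds are never touched |

One global seed derives independent substreams (fold shuffle, negative
sampling, initialisation, dropout) so every component is reproducible in
isolation and end-to-end.

## Training protocol

One BPR triple per training positive per epoch, with the unobserved j
resampled every epoch (a saturated circRNA — adjacent to every miRNA in
training — yields no triples and is skipped with a warning). Parameters are
Glorot-uniform initialised. The early-stopping snapshot is the
best-validation-AUC epoch; with a degenerate (single-class) validation set
the criterion falls back to training loss with a warning, and with
val_fraction = 0 training simply runs the full budget. Propagation degrees
and the normalised adjacency always come from the training split of the
fold being fitted — cold-start nodes whose every edge fell into the test
split keep degree 0 and receive only self-messages, which avoids leaking
split information.

Cross-validation partitions the positives into five near-equal parts by a
seeded shuffle. Negatives are drawn fresh per fold, uniformly from pairs
outside the full positive set, one per positive for both the training and
the test role, with the four sets of a fold pairwise disjoint. Whether a
single global negative set or per-fold resampling is intended by the
original experimental description is ambiguous; per-fold resampling is the
default here as the more conservative reading, and a fixed external
negative list can be supplied through `cmipred evaluate`.

## Metrics and numerical choices

- AUC: rank-based (Mann–Whitney) with midranks, so tied scores count ½.
- AUPR: average precision by step-sum over recall increments, tied scores
  entering as one threshold group. Trapezoidal PR interpolation is avoided
  because it overestimates the area.
- Acc/Pre/Recall/F1: predict interaction iff score ≥ threshold; the
  threshold the published tables used is unstated, so it is exposed as a
  flag with default 0 on the raw inner product (= sigmoid ≥ 0.5). Zero
  denominators are reported as undefined rather than silently zeroed.
- Candidate ranking normalises scores min–max over the scored candidate set
  (sigmoid available by flag — which of the two the published case studies
  used is unstated); ties break by candidate index, ascending, so top-k
  lists are reproducible.
- Sorts that feed ranking or edge selection are stable; ties in the
  synthetic generator's top-density cut break by flat pair index.
- Gradients are hand-derived (the score gradient scatters onto every
  layer's embeddings, then backpropagates through the recursion); the test
  suite checks them against central finite differences at rel. error 1e-4,
  and the vectorised sparse forward pass against an explicit-loop dense
  oracle at 1e-6. Inverted dropout (rescale by 1/(1−p) at train time) keeps
  evaluation-mode expectations aligned without rescaling at inference.

## Synthetic benchmark

The generator plants low-rank structure: i.i.d. standard-normal latent
factors per node, affinity = inner product, edges = the top density·n·m
affinities, then independent membership flips with probability p. It
emulates exactly what the model exploits (a low-rank interaction
propensity observed through a sparse, lightly noisy catalogue) and nothing
else: identifier vocabularies, hub-heavy real degree distributions, and
study-bias artefacts of curated databases are *not* reproduced. Passing the
recovery tests therefore shows the pipeline can recover plantable latent
structure through training, splitting and scoring — it does not certify
performance on any real catalogue.

Default generator conditions: n=200, m=100, rank 4, density 0.05 (≈1,000
edges, ≈5 per circRNA — the sparsity regime of curated interaction data),
flip probability 0.01. At these settings the hidden-affinity ranking itself
is capped near AUC ≈ 0.92 (a flipped-in edge carries a random affinity), so
model AUCs must be read against that ceiling, not against 1.0.

For experiments at this 200×100 size (tests and `scripts/acceptance.py`)
the model runs with D=32, K=2, batch 256, λ=1e-4, up to 800 epochs with
patience 80: capacity and budget proportionate to a thousand-edge graph,
where D=256 would be badly over-parameterised. Five-fold cross-validation
of the full pipeline completes in well under a minute on one CPU at these
sizes.

## Known limitations

- The numpy implementation is single-threaded per matmul and sized for
  catalogue-scale graphs (thousands of nodes); it is not a GPU trainer.
- Only association topology is used; truly novel nodes (no training edges)
  receive self-message-only embeddings and their rankings are
  uninformative — the method cannot do cold-start prediction from sequence.
- Negative "truth" in evaluation is sampled from unlabeled pairs, so all
  reported discrimination metrics are relative to the
  missing-not-observed assumption.
- Reported thresholds metrics at the default threshold 0 favour recall
  over precision when scores skew positive; threshold calibration is left
  to the user because the appropriate operating point depends on the
  follow-up budget.
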