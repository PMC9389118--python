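# cmipred

Graph-convolutional link prediction for circRNA–miRNA interaction networks.

Circular RNAs (circRNAs) act as molecular "sponges" for microRNAs (miRNAs):
by binding miRNAs they modulate the regulatory pressure those miRNAs exert
on messenger RNAs, with documented consequences in cancer and metabolic
disease. Experimentally validated circRNA–miRNA interactions are scarce and
expensive to obtain, so the catalogued interaction network is a sparse
sample of the true one. `cmipred` is for computational biologists who want
to prioritise unvalidated circRNA–miRNA pairs for experimental follow-up
using *only* the topology of the known interaction network — no sequence
features, no precomputed similarity matrices.

## Model

Known interactions form a bipartite graph G(U ∪ V, E) over n circRNAs and
m miRNAs, equivalently a binary interaction matrix R ∈ {0,1}^{n×m}. Every
node carries a trainable D-dimensional embedding e⁰. K embedding-propagation
layers refine them by message passing (NGCF-style): at layer k,

    e_u^k = LeakyReLU( W₁ᵏ e_u^{k-1}
            + Σ_{v∈N(u)} (1/√(|N(u)||N(v)|)) · ( W₁ᵏ e_v^{k-1}
                                                + W₂ᵏ (e_v^{k-1} ⊙ e_u^{k-1}) ) )

and symmetrically for miRNAs; ⊙ is the elementwise product, the
1/√(|N(u)||N(v)|) factor is the graph-Laplacian decay, and the self-message
carries no decay. The final representation concatenates all layers,
e\* = e⁰‖e¹‖…‖e^K, and a pair is scored by the inner product ŷ(u,v) =
⟨e_u\*, e_v\*⟩, so each layer contributes the interaction signal of one
additional hop.

All parameters Θ = {E⁰, W₁ᵏ, W₂ᵏ} are trained end-to-end with the Bayesian
Personalized Ranking objective

    L(Θ) = Σ_{(u,i,j)} −ln σ(ŷ_ui − ŷ_uj) + λ‖Θ‖₂²,

where (u,i) is a known interaction and (u,j) an unobserved one — the model
learns to *rank* observed partners above unobserved ones rather than to
regress labels. Optimisation is Adam with message/node dropout;
evaluation is five-fold cross-validation with balanced negative sampling
(AUC, AUPR, Acc/Pre/Recall/F1). A planted low-rank synthetic benchmark
makes the whole pipeline testable without any external download.

The forward pass, analytic backpropagation and Adam are implemented
directly on numpy/scipy sparse matrices; gradients are verified against
central finite differences in the test suite.

## Worked example

Simulate a 200×100 interaction network with rank-4 latent structure (5%
density, 1% label noise), then cross-validate the model on it:

```
cmipred simulate --seed 1 --out demo
cmipred cv --edges demo/edges.tsv --k 5 --dim 32 --k-layers 2 \
    --max-epochs 800 --patience 80 --batch-size 256 --lambda-reg 1e-4 \
    --seed 1 --out demo/cv
```

`demo/cv/metrics.json` then contains (abridged):

```
"average": {
  "auc":  0.8258,
  "aupr": 0.8549,
  "recall": 0.9735,
  ...
}
"per_fold": [0.8041, 0.8240, 0.8198, 0.8468, 0.8345]   # AUC column
```

Mean AUC 0.826 means that a held-out true interaction outranks a random
non-interacting pair 83% of the time — far above the ~0.5 of chance and
above the degree-product popularity baseline, though below the ≈0.92
ceiling set by the 1% label noise. Training a full model and ranking
candidate partners for one miRNA (the case-study protocol: known partners
removed, scores min–max normalised):

```
cmipred train --edges demo/edges.tsv --dim 32 --k-layers 2 --max-epochs 300 \
    --patience 40 --batch-size 256 --lambda-reg 1e-4 --seed 1 --out demo/model
cmipred rank --checkpoint demo/model/checkpoint.npz --query mir_7 --top-k 5
rank  id        score
1     circ_121  1.0000
2     circ_61   0.9065
3     circ_180  0.8789
4     circ_145  0.8287
5     circ_128  0.8246
```

Real data goes through the same commands: any two-column TSV/CSV edge list
of circRNA/miRNA identifiers works as `--edges`, and `cmipred evaluate`
scores an external positive list against a frozen checkpoint.

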