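# graphomix

Supervised integration of multi-omics data over prior-knowledge graphs,
with attribution-based biomarker discovery under permutation-controlled
false discovery rates.

## The problem

Bulk multi-omics case/control studies (e.g. transcriptomics + proteomics in
an Alzheimer's cohort) measure thousands of features on a few hundred
participants, and the modalities rarely cover the same samples.  graphomix
addresses three problems at once:

1. **Dimensionality** — each sample is encoded as one *feature graph per
   modality*: nodes are genes/proteins carrying the sample's measurements,
   edges come from a prior-knowledge network (e.g. a shortest-path
   subnetwork of a protein–protein-interaction database restricted to a
   functional gene set).  A graph neural network (GNN) exploits the
   correlation structure along edges, so hundreds of samples suffice for
   thousands of features.
2. **Integration with missing modalities** — per-modality embeddings
   `z_i = g_i(x_i, E_i, W_i) ∈ R^m` are aligned across modalities (by
   maximizing per-dimension |Pearson r|) and fused by a **class-token set
   transformer**: `ŷ = MLP(Encoder(z_0, z_1, …, z_K)_0)`.  Samples missing
   a modality are routed through per-modality MLP heads, so every sample
   contributes to training.
3. **Interpretation** — **integrated gradients**
   `φ_i = (x_i − x'_i) ∫₀¹ ∂f_c(x' + α(x − x'))/∂x_i dα`
   attribute predictions to input nodes against a control-mean baseline,
   and **integrated Hessians**
   `Γ_ij = (x_i − x'_i)(x_j − x'_j) ∫∫ αβ ∂²f_c/∂x_i∂x_j dα dβ`
   score pairwise interactions (with `Γ_ii = φ_i − Σ_{j≠i} Γ_ij`, so row
   sums reproduce φ).  A marker is called informative when its score
   exceeds a threshold `d` chosen so that the permutation-based empirical
   FDR
   `FDR(d) = π₀ · (Σ_b |{i: φ_i^(b) > d}| / B) / |{i: φ_i > d}|`
   stays below a target (default 0.05), where the `φ^(b)` come from `B`
   models retrained on label-permuted data.

The GNN encoder stack is: community positional encoding → community-weighted
graph convolutions (symmetric-normalized message passing with residuals,
batch normalization, and optional top-k node masking capping the active
node count) → memory pooling onto learnable centroids → residual projection
to an m-dimensional embedding.  The neural-network core, including the
reverse-mode autodiff engine with the double-backward support integrated
Hessians require, lives in `graphomix.autodiff` / `graphomix.nn` and runs
on numpy.

## Worked example

```bash
python examples/discover_markers.py
```

trains the integrated model on a simulated cohort (300 complete + 100
transcriptomics-only + 50 proteomics-only samples, 100-node scale-free
prior graphs, 10 planted markers with a 2-SD case/control shift), builds a
permutation null pool from 6 label-permuted retrainings, and prints:

```
validation accuracy: 1.000 (150 correctly predicted validation samples)
  rna: |phi| threshold 0.487, estimated FDR 0.0498...
  protein: |phi| threshold 2.243, estimated FDR 0.0423...
 rank symbol  mean_fraction  total_samples  n_samples_simulated
    1  G0016       0.626667             94                   94
    2  G0039       0.613333             92                   92
    3  G0096       0.600000             90                   90
    ...
planted markers among the top 10: 10/10
```

`mean_fraction` is the share of correctly predicted validation samples in
which the marker's attribution magnitude cleared the FDR-controlled
threshold; all ten planted markers rank at the top.  Other examples cover
cohort simulation, training against unimodal baselines, shortest-path prior
construction, and biodomain-interaction ranking via integrated Hessians.

A thin CLI mirrors the library for shell use:

```bash
graphomix simulate --config config.yaml --outdir run/
graphomix train    --config config.yaml --outdir run/
graphomix explain  --config config.yaml --outdir run/
```

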