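# Methods

## Model

Each omics modality `i` contributes a feature vector `x_i ∈ R^{d_i}` and an
undirected prior graph `G_i` over the same `d_i` symbols.  The encoder
`g_i` maps `(x_i, G_i)` to an embedding `z_i ∈ R^m`:

1. **Community positional encoding.**  A lookup table assigns each node a
   softmax-normalized membership over `c` learnable communities
   (`p ∈ R^{d_i × c}`, row-stochastic).  The input scalar per node is
   lifted to `C` channels by a community-weighted linear map
   `ĥ_j = Σ_k p[j,k] · (h_j W_k)`, where each community has its own
   `C_in × C_out` weight block.  With `c = 1` this is a plain linear layer.
2. **Graph convolution blocks** (`N` of them).  Each block applies the
   community-weighted map followed by symmetric-normalized message passing
   with unit self-loops, `h_out = D̂^{-1/2}(A + I)D̂^{-1/2} ĥ + b`, a ReLU,
   a residual add of the block input (hence `C_in = C_out` inside blocks),
   and batch normalization.  Blocks may end with **top-k masking**: nodes
   are scored by a learnable vector, the top `⌈ratio·n⌉` stay active, and
   surviving features are gated by a sigmoid of their scores.  Per-block
   ratios follow `(node_cap/d_i)^{1/N}` with floor/clamping so that at most
   `node_cap` (default 300) active nodes reach pooling.
3. **Memory pooling.**  Active-node features are softly assigned to `d_c`
   learnable centroids with `S = softmax(−‖x̃_j − μ_k‖²)` (rows
   nonnegative, summing to one) and pooled to `Sᵀx̃`, then linearly mapped
   to `d_i' ` channels — a fixed-size coarse representation independent of
   the active-node count.
4. **Residual embedding.**  `z_i = Linear_m(flatten(z') + Linear(x_i))`,
   adding a linear projection of the raw input.

**Integration.**  Embeddings form a token set with a learnable class token;
`n` standard transformer encoder blocks (multi-head self-attention →
residual + layer norm → tokenwise shared FFN → residual + layer norm, no
positional encodings) process the set, and an MLP head maps the class
token's representation to class scores.  The absence of positional
encodings makes the readout invariant to modality order.  Each modality
additionally has an MLP head over its own embedding for samples missing the
other modality.

**Loss.**  `L = Σ_i L_i + λ₁L_int + λ₂Σ_{i>j}L_align + λ₃L_reg` with
class-weighted softmax cross-entropy prediction losses (weights are inverse
class frequencies normalized to mean one), an alignment loss, and an L2
penalty over weight matrices (biases and normalization offsets excluded).
The default alignment term uses complete samples only: per embedding
dimension, the Pearson correlation of `z₁[:, j]` with `z₂[:, j]` across the
batch, loss `−mean_j |r_j| ∈ [−1, 0]`, zero-variance dimensions
contributing 0.  A cross-pair variant (correlating same-label sample pairs
across modalities over the m dimensions) is implemented and opt-in via
`alignment_mode="complete_plus_crosspair"`; the default is the
complete-only form because single-modality training subsets set the
alignment term to zero.  Training on incomplete cohorts partitions samples
into availability subsets (complete / modality-1-only / modality-2-only);
one epoch is one pass over each subset, subset order redrawn per epoch from
the seeded generator; single-modality subsets contribute only their
unimodal prediction loss, so integrator gradients are exactly zero there.
Optimization uses Adam (default lr 1e-3, batch 16, 200 epochs — all
configurable; the bundled tests and examples use 4–20 epochs and widths of
2–4 channels, which suffice at their problem sizes).

Model selection uses stratified 3-fold cross-validation with 3 weight
initializations per split (9 trials per configuration); configurations are
scored by mean validation accuracy, ties broken by lexicographic config
order.  Accuracy counts argmax-correct predictions, integrated for complete
samples and unimodal for single-modality samples.

## Attribution and discovery

Integrated gradients use a midpoint Riemann sum over the straight path from
a baseline `x'` (per-feature mean of training controls) to `x`.  Integrated
Hessians evaluate the off-diagonal interaction integral by a nested
midpoint rule (default 50 steps per axis; second derivatives come from
differentiating the gradient graph again) and define the diagonal by the
remainder `Γ_ii = φ_i − Σ_{j≠i}Γ_ij`, so row sums reproduce φ exactly and
the identity survives summation into token-level blocks.  Attribution runs
in evaluation mode (frozen normalization statistics) with top-k masks
recomputed per input and gradients flowing through the sigmoid gates.

Two numerical choices matter and are deliberate:

* **Attributed score.**  For a two-class softmax head, only the log-odds
  `f₁ − f₀` is constrained by training; the common-mode of the logits is
  arbitrary and adds noise to attributions of a single logit.  The default
  score is therefore the margin toward the disease class (class 1); a
  `score="logit"` option attributes the raw class-1 logit.
* **Matched null statistic.**  Null attribution scores come from models
  retrained on label-permuted training data but are computed **on the same
  validation samples** as the observed scores.  Attributing the null
  models' own training samples would inflate the null pool with
  memorization effects and destroy discovery power.  The null pool is
  reusable across analyses of the same dataset (folds, initializations).

The empirical FDR at threshold `d` is
`π₀ · (mean over null models of #{scores > d}) / #{observed > d}` with
`π₀ = 0.97` by default.  Candidate thresholds sit just below each unique
observed score — FDR only changes at observed values, and placing the
candidate infinitesimally below makes the score itself discoverable under
the strict inequality — and the smallest candidate at or under the target
is selected.  If none reaches the target, the minimum attainable FDR is
reported and nothing is called.  Marker calling uses |φ| (configurable to
signed scores) and only correctly predicted validation samples; per-study
ranking counts unique sample identifiers per gene across modalities and
analyses, divides by the study's correctly predicted validation count, and
ranks by the mean fraction across studies (ties: total samples, then
symbol).  Per (modality, graph) analyses keep separate thresholds.

Biodomain-interaction analysis trains an auxiliary class-token set
transformer on per-domain class-token embeddings of complete samples,
scores unordered domain pairs by the magnitude of the symmetrized
token-level interaction `|Γ_ij + Γ_ji|`, thresholds by permutation FDR,
counts informative samples per pair, and retains pairs appearing in the
per-repeat top 10% in at least 3 of the repeats (default 10), ranked by
appearance count then total informative samples.  Two safeguards keep the
interaction null pool honest at desk scale: interactions (observed and
null alike) are scored on a held-out stratified third of the samples, and
the auxiliary training applies an L2 weight penalty (default 1e-2) —
without both, a label-permuted retraining is free to memorize its
training set with a sharply curved decision surface whose Hessian
magnitudes swamp the observed model's, and nothing is ever called.
Token-level interaction matrices are computed with one double-backward
pass per token (the per-sample path offsets folded into the differentiated
scalar), so whole cohorts are scored in a handful of passes.

## Synthetic cohorts

The generator emulates the structure of a two-modality brain cohort:
unequal feature counts, partial sample overlap (complete plus two
single-modality groups), case imbalance (default case fraction 0.6,
matching case:control ratios near 1.5–2:1), and a planted predictive
subset.  Features are standard Gaussian noise diffused one step over the
symmetric-normalized adjacency and mixed with the i.i.d. component at
weight `within_graph_corr`, which links correlation to adjacency; planted
nodes (symbols shared across modalities, mimicking gene↔protein pairing)
receive a mean shift of `effect_size` in cases after smoothing, and in
complete samples draw from a common latent at weight
`cross_modality_corr`.  All randomness flows through one generator seeded
per call; identical arguments give byte-identical outputs.  The generator
makes no attempt to model realistic abundance distributions, batch effects,
or platform noise, so passing tests demonstrate correctness of the
machinery and recoverability of planted structure — not performance on real
cohorts.

Default study conditions used by the test suite and acceptance script: 300
complete + 100 + 50 incomplete samples, 100-node scale-free graphs, 10
informative nodes, effect size 2; FDR calibration uses label-independent
cohorts of 200 samples with 50 permutation models and encoder widths of 2
channels.  These sizes are the package's chosen desk-scale study
conditions.

## Preprocessing and labeling

Case/control labels combine cognition scales with neuropathology: dementia
iff MMSE ≤ 24 (when present) or CDR ≥ 1 (when present); AD iff CERAD ∈
{2,3}, Braak ∈ {3..6}, and dementia; control iff CERAD ∈ {0,1}, Braak ∈
{0..3}, no dementia, and (Braak = 3 ⇒ CERAD = 0); everything else is
excluded.  Feature preprocessing applies log2(x + pseudocount) (default
pseudocount 1, skippable for already-transformed abundances), per-feature
median centering, then OLS residualization on covariates (age, sex,
post-mortem interval; categorical covariates one-hot encoded; samples with
missing covariates excluded from the fit but residualized with the fitted
coefficients; rank-deficient designs rejected naming the offending column).
The order log2 → center → residualize is a documented package choice.

## Numerical infrastructure

The NN core is a compact reverse-mode autodiff engine over float64 numpy
arrays.  Backward rules are themselves built from primitives, so
double-backward (needed for integrated Hessians) works by construction.
2D-versus-batched matrix products are routed through single BLAS calls via
reshape/transpose compositions; `exp`/`tanh`/`sigmoid` recompute their
primal in backward rather than capturing their output, keeping the tape an
acyclic, promptly-reclaimed structure; `exp` inputs are clipped at ±700 to
avoid over/underflow.  Batch normalization uses running statistics in
evaluation mode so attributions are deterministic.

## Known limitations

* Top-k masking gates features on a fixed topology rather than rebuilding
  an induced subgraph; message-passing normalization keeps full-graph
  degrees.  Active-node contracts (counts, cap before pooling) hold.
* Edge weights must be scalar and nonnegative; directed graphs and
  edge-feature updates are unsupported.
* The incomplete-sample scheduler assumes at most two modalities in the
  bundled analyses; the architecture itself accepts K > 2.
* Training is single-process CPU; there is no early stopping.
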