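# Methods

`scregnet` infers gene regulatory networks (GRNs) from paired single-cell
RNA + ATAC (multiome) data by fitting one small neural network per target
gene (TG) and reading regulatory structure out of the fitted models. This
note documents the model, the estimation procedure, the synthetic study the
package tests itself against, and the numerical choices that are not forced
by the science.

## Model

For gene *i*, expression is predicted from the expression of all
transcription factors (TFs) and the chromatin accessibility of candidate
regulatory elements (REs) whose midpoint lies within 1 Mb of the TSS:

    E_i ≈ f([E_TF ; O_window(i)], θ)

`f` is a fully connected network with hidden layers of 64 and 16 ReLU units
and a linear scalar output. TF self-regulation is excluded (a TF is never a
feature of its own model). Genes with no candidate REs are modeled on TFs
alone; genes with near-zero expression variance are skipped and logged.

Training happens in two stages:

1. **Bulk pre-training.** The model is fit to a bulk atlas (many samples
   spanning diverse cellular contexts) with MSE + λ0·L1. The diagonal
   Fisher information of the first-layer weights — the mean squared
   per-sample gradient of the squared error — is recorded as a measure of
   how much the bulk data constrains each weight.
2. **Consolidated refinement.** Starting from the pre-trained weights, the
   model is refit on single-cell metacells with

       L = λ1·MSE + λ2·L1 + λ3·tr(W1ᵀ L_norm W1) + λ4·EWC.

   The third term is manifold regularization: `L_norm` is the normalized
   Laplacian of the bipartite TF–RE graph weighted by motif binding
   affinity, so TF and RE features whose motif evidence links them are
   pulled toward shared first-layer embeddings. The fourth term is elastic
   weight consolidation (EWC): the Fisher-weighted mean squared difference
   between refined and pre-trained first-layer weights, which lets the
   single-cell fit adapt where the bulk data was uninformative while
   retaining what it pinned down.

Defaults: λ0 = λ2 = 1e-3, λ1 = 1, λ3 = 0.01, λ4 = 1; Adam, learning rate
1e-3, full batch, at most 500 epochs with early stopping (patience 20 on
the training loss, best parameters kept). Inputs are log1p-transformed and
z-scored per feature within each domain (bulk statistics for the bulk
stage, metacell statistics for refinement); targets are log1p expression.
Standardizing per domain keeps the L1 and EWC scales comparable across
features; the per-gene scaler is retained so interventions can map raw
zero expression through the same transform.

**Fisher scaling.** Raw squared-gradient magnitudes differ by orders of
magnitude between genes (they track the residuals of the bulk fit), so a
single λ4 would be vacuous for some genes and rigid for others. The
pipeline therefore rescales each gene's Fisher matrix to unit mean before
refinement; λ4 then measures consolidation strength in units of "average
bulk constraint". The EWC penalty itself is the textual squared-difference
form; the alternative product form is available behind `ewc_form="product"`
but is unbounded below and not usable as a penalty.

## From fitted models to a GRN

* **Trans (γ, TF→TG) and cis (β, RE→TG) strengths** are mean absolute
  Shapley values of the corresponding input features across metacells.
  Shapley values are estimated by permutation sampling (default 200
  permutations, antithetic pairs, baseline = per-feature mean of the
  training metacells); when the budget covers all n! feature orders the
  sampler enumerates them and is exact. An independent 2^n
  subset-enumeration oracle validates the sampler in the test suite.
* **Binding strength (α, TF→RE)** is the Pearson correlation between the
  64-dimensional first-layer weight rows of the TF and RE features. When a
  TF–RE pair appears in several gene windows, the entry with maximum
  absolute value (sign preserved) is kept.
* **Cis/trans dominance** per gene compares per-sample mean |Shapley| of RE
  features vs TF features (two-sided unpaired t-test, Bonferroni across
  genes).

## Context-specific networks

Cell-type (and cell-level) networks combine context-independent quantities
(γ, β, α, motif affinity B, RE–TG distance) with context expression E and
accessibility O:

    TFB_kj = C_kj^{s_k} · E_k · O_j · (α_kj + B_kj)
    CRP_ij = β_ij · O_j · E_i · exp(−d_ij / d0),   d0 = 25 kb
    TRP_ki = γ_ki · Σ_{j ∈ window(i)} TFB_kj · CRP_ij

C_kj is the TF–RE correlation across the type's metacells (configurable to
all metacells); s_k is the TF importance score built from motif enrichment
(hypergeometric, over the top cell-type-specific REs) and permutation
z-scores of TF–RE correlations. `C^s` is ill-defined for negative C or s,
so C is clamped to [0,1], s to ≥ 0, with 0^0 := 1; (α + B) is floored at 0.
These clamps keep all potentials nonnegative, which the cumulative TRP sum
requires. Cell-level networks reuse the type-level C and s (they need a
population of samples) with that cell's E and O.

The genome-scale default of 5,000 cell-type-specific REs is kept as the
operation default; the synthetic studies pass a proportionally smaller
number (50 of 200 REs) because the fixture's RE universe is three orders
of magnitude smaller than a genome-wide peak set.

## Downstream analyses

* **GWAS traits.** A SNP links to a gene when the TSS falls in the 200-kb
  window centered on the SNP; each gene receives the most significant
  linked p-value, Benjamini–Hochberg adjusted (the adjustment method is the
  package's choice; a gene-level screen warrants FDR rather than FWER
  control). Trait genes are adjusted p < 0.01. Per TF, the overlap of its
  top-1000 TRP-ranked targets with the trait set is z-scored across TFs;
  key TFs are ranked by expression z + regulation z. On the synthetic
  fixture the target-list length is scaled to 20 of 60 genes for the same
  reason as above.
* **Regulon activity.** Trans scores are quantile-normalized across TFs;
  each TF's top-1000 genes form its regulon; per sample the activity is the
  normalized area under the recovery curve of regulon genes within the top
  5% of the expression ranking — a rank-based enrichment in [0,1],
  invariant to monotone transforms of expression.
* **In silico knockout** sets a TF's raw expression to zero (pushed through
  the model's own log1p/z-score transform — the intervention is on the
  measurement scale, not the z-score scale) and reports the change in
  predicted expression per gene and sample.

## The synthetic study

The generator plants a ground-truth network and emulates the forward model
the method assumes; every pipeline stage is exercised on data whose truth
is known. Defaults (one "study"): 10 TFs, 60 TGs, 200 REs on one synthetic
chromosome (TSSs every 250 kb; each RE within 100 kb of a home gene),
5 cell types × 200 cells, 150 bulk samples, Poisson counts at ~5,000 reads
per cell, multiplicative activity noise of 0.1.

Design choices that matter:

* **Truth sparsity.** TF→RE binding and direct TF→TG edges are Bernoulli
  with density 0.03, giving each gene roughly one planted regulator
  (positive fraction ≈ 0.10 of TF–TG pairs). This matches the sparse-truth
  regime in which precision-recall-based benchmarks of GRN methods are
  meaningful; dense truths push the random-predictor AUPR so high that the
  AUPR ratio cannot distinguish methods.
* **Bulk diversity.** Bulk samples mix freshly drawn synthetic cell types
  (Dirichlet weights over three new activity profiles per sample) rather
  than the five types present in the single-cell data. An atlas's value is
  exactly that it spans contexts the single-cell experiment does not; with
  mixtures of only the five single-cell types, all TF activities would be
  collinear (rank ≤ 5) and no method could attribute targets to the right
  TF among correlated ones.
* **Imperfect motif evidence.** A bound TF–RE pair carries the TF's motif
  consensus with probability 0.9; an unbound pair with probability 0.05
  (spurious scan hits). Motif scans on real sequence are informative but
  noisy in both directions, and this noise is what bounds how strongly the
  manifold regularization can be leaned on.
* **Observation model.** Softplus link and Poisson counts; negative
  binomial available via `count_model="negative_binomial"`.

What the generator does *not* emulate: realistic dropout calibration,
batch effects, doublets, sequence-composition biases, TF cooperativity
beyond additive effects. Passing tests therefore demonstrate internal
correctness and recovery under the stated generative assumptions, not
performance on real multiome data.

## Metacells

Per annotated cell type, ceil(sqrt(n)) seed cells are sampled without
replacement and each is replaced by the average of its 100 nearest cells
(Euclidean distance in the top-50 PCs of log1p, depth-normalized
expression). Neighbors are found in RNA space only and may cross cell-type
labels; `within_type=True` restricts the pool. Averages are taken on raw
counts, so identical cells yield the common profile exactly.

## Numerical choices and degenerate inputs

* Normalized Laplacian: isolated nodes get zero row/column/diagonal;
  computed as A / sqrt(d_i d_j) so small integer-degree cases are exact.
* L1 is handled by subgradient (sign(0) = 0) added to the Adam gradient.
* Zero-variance embeddings → α = 0 with a warning; zero-variance vectors in
  permutation z-scores → z = 0; degenerate group variance in t-tests →
  p = 1.
* Ties: candidate REs order by (distance, re_id); RE specificity and
  key-TF rankings break ties by id; quantile normalization maps tied ranks
  to interpolated reference values.
* Determinism: every stochastic step draws from a generator seeded from an
  explicit seed; per-gene seeds derive from the master seed via
  `SeedSequence` so results are independent of gene iteration order.

## Problem sizes

The self-contained studies run at the scale above (60 genes) for the
recovery analyses, with a smaller 10-gene configuration for integration
tests. At these sizes a full train-extract cycle takes on the order of a
minute per method on one CPU core, and the complete ablation (five seeds,
both routes) under ten minutes.

## Known limitations

* On the synthetic fixture, recovery does not degrade when the manifold
  weight λ3 is pushed far above its default (the planted motif graph, even
  with false positives, stays dominantly informative at a 200-RE scale, and
  most planted TF→TG edges run through REs, so embedding alignment keeps
  helping). Over-regularization harm is a genome-scale motif-noise
  phenomenon the generator does not emulate; the default λ3 = 0.01 is kept
  and only its advantage over λ3 = 0 is asserted in the tests.
* The Shapley γ attributes only the direct path of a TF to the model
  output; TF effects mediated purely through RE accessibility are credited
  to the REs. Recovery of path-only TF→TG edges rests on the correlation
  between TF expression and its REs' accessibility.
* Permutation z-scores share one permutation per iteration across REs;
  this is unbiased per pair but correlates the null draws between REs of
  the same iteration.
* The CLI is single-threaded; `--threads` is reserved.
* Checkpoint `.npz` files store the training design matrix for later
  attribution/knockout; for genome-scale runs this would need a leaner
  format.
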