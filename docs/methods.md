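# Methods

## Model

spotdeconv treats spot deconvolution as supervised composition
regression. Let the reference contain K cell types. A simulated
pseudo-spot with composition p on the K-simplex is the element-wise sum
of the raw count vectors of n cells drawn (uniformly, with replacement,
within type) according to the largest-remainder rounding of p·n; the
stored label is the realised post-rounding composition, so training
targets are exact. The network f maps the normalised expression vector
x of a profile to a predicted composition f(x) ∈ Δ^(K−1).

The core assumption is the usual one for reference-based deconvolution:
a spot's expression is approximately the sum of the expressions of its
member cells, and those cells are transcriptionally exchangeable with
reference cells of the same type. Platform effects between the scRNA-seq
reference and the ST assay (capture efficiency, spot-size variation,
lateral transcript diffusion) are not modelled.

### Normalisation

Counts-per-10,000 per column followed by log(1 + x), applied
identically to training mixtures, intrinsic spot profiles and extrinsic
neighbourhood profiles. The shared scheme is what matters: the network
only ever sees inputs from the same distribution it was trained on.
All-zero columns are left at zero. The gene space is the lexicographic
intersection of reference and ST gene ids, optionally filtered by total
reference counts, expressing-cell fraction, and a user regex (e.g.
mitochondrial/ribosomal genes; off by default since there is no
universally right choice).

### Composition sampler

Dirichlet(α = 1) by default, with 10% pure one-hot profiles (cycling
through the types) and 30% sparse profiles in which a uniformly chosen
non-empty strict subset of types is zeroed before the Dirichlet draw.
The strata guarantee the network sees simplex vertices and faces, not
just the interior — real tissue contains near-pure regions, and a
sampler without them systematically under-predicts extreme
compositions. Mixtures contain 50 cells by default (spot-scale for
Visium-like platforms; configurable).

### Network and training

Fully connected, two hidden layers of 200 ReLU units (PReLU optional),
inverted dropout 0.25, softmax output head. Default loss is the KL
divergence from true to predicted composition (MSE/MAE available);
with the softmax head its logit gradient is the simple residual p − y.
Optimised with AdamW (learning rate 1e-3, decoupled weight decay 1e-4
on weight matrices), batch 64, at most 60 epochs, early stopping on a
10% validation split with patience 10, best-epoch weights restored. All
randomness (init, shuffling, dropout masks) flows from one seed and the
implementation is pure numpy, so training is bit-deterministic for a
fixed seed — two identically seeded runs write identical proportion
tables.

`input_dropout` (default 0) additionally drops input genes during
training. It is off by default because input-noise training slightly
shrinks predictions toward the uniform composition (costing
concordance), but it is the recommended setting (≈ 0.1) when the goal
is interpretation or when the ST assay is missing many reference genes:
marker genes of one type are strongly collinear across mixtures, so an
unconstrained network may lean on an arbitrary subset of them, whereas
gene dropout forces the weight to spread over the whole redundant
block, which both stabilises attribution rankings and hardens the model
against zero-filled genes at prediction time.

Prediction reindexes any input count matrix to the model's gene space
(zero-filling missing genes, warning below 90% coverage, refusing at
zero coverage), normalises it with the stored spec, and applies the
forward pass; outputs are exactly row-stochastic.

### Spatial regularization

The spatial graph is the exact k nearest neighbours per spot under
Euclidean distance (brute-force pairwise distances; ties broken by spot
index so degenerate layouts are deterministic). Default k = 6 suits
hexagonal lattices (Visium); use k = 4 on square grids. The extrinsic
profile of spot i is the unweighted raw-count sum over its k
neighbours, deconvoluted by the same trained network. With
d_i = 1 − similarity(intrinsic_i, extrinsic_i) (cosine by default, on
normalised profiles, min-max rescaled to [0, 1] across spots),

    λ_i = λ_max (1 − d_i),    regularized_i = (1 − λ_i) intrinsic_i + λ_i extrinsic_i.

The blend is convex, so outputs stay on the simplex; λ_max = 0 is a
bit-exact identity. The step assumes transcriptional continuity between
neighbouring spots and is therefore optional and off by default — on
tissues with sharp interdigitated structures it can only blur.

### Attribution

Input gradients are exact (explicit backward pass, no dropout at
attribution time). Two scores per gene and type: gradient × input
(mean over profiles of ∂f_t/∂x_g · x_g) and integrated gradients from
an all-zero baseline (midpoint Riemann rule, default 50 steps; the
completeness identity Σ_g a_g = f_t(x) − f_t(0) converges as steps
grow). Scores should be averaged over profiles in the simplex
*interior*: at pure profiles the softmax saturates (f_t ≈ 0 or 1), its
gradients vanish, and the ranking degenerates to noise. The CLI and
tests therefore average over full-Dirichlet mixtures rather than the
pure profiles one might first reach for.

### Metrics

Pearson correlation (PCC), Lin's concordance correlation
(CCC = 2 cov(x,y) / (var x + var y + (mean x − mean y)²), population
1/n moments, so the identity limits are exact; two equal constant
vectors give 1 by convention), RMSE, and Jensen–Shannon divergence with
base-2 logs (range [0, 1]; inputs renormalised; 0·log 0 = 0). CCC is
the stricter headline metric: it penalises distance from the identity
line, not just non-linearity, so a systematically biased predictor can
have PCC ≈ 1 and CCC ≪ 1. Per-type metrics are computed across
profiles; the overall report averages them across types, plus the mean
per-profile JSD. Clustering of spots on predicted compositions is
Euclidean k-means with 10 restarts keeping the lowest inertia.

## The synthetic generator

`make_reference` draws counts from a negative binomial with mean
base · fold^(marker) · library-factor: constant baseline rate
(default 2 counts/gene), disjoint marker blocks of 25 genes per type at
fold-change 8, NB size 2 (strong overdispersion), and a lognormal
per-cell library factor with CV 0.2. `make_spatial` places spots on a
lattice split into vertical composition regions (Dirichlet draws around
per-region archetypes, concentration 15, zero archetype entries staying
exactly zero) and synthesises spot counts through the same mixture
machinery (10 cells/spot by default). `make_single_cell_st` scatters
labelled cells over the unit square with region-dependent type
frequencies; `bin_single_cell_st` aggregates them into square bins
whose true compositions are the member-type frequencies — the standard
way to score deconvolution on imaging-based (seqFISH/STARmap-like)
data, with bin geometry chosen square for determinism and exact count
conservation.

What the generator does *not* emulate: per-gene baseline heterogeneity
and gene–gene correlation beyond type structure, ambient RNA/doublets,
platform-specific capture differences between reference and spots, and
real marker overlap between related cell types (blocks are disjoint).
Recovery numbers on these fixtures are therefore an upper bound on
real-data performance: they show the pipeline is correct and the types
identifiable, not that any particular tissue will deconvolute at the
same accuracy.

## Problem sizes

The self-evaluation run (also what `scripts/acceptance.py` reproduces)
uses the default reference — 5 types × 200 cells, 500 genes — with
2,000 training and 500 test mixtures of 50 cells; it trains in seconds
on one CPU and reaches mean per-type PCC/CCC ≈ 0.99/0.99. The
binning protocol uses 2,000 cells in two regions aggregated to ≈ 200
spots. Test-suite fixtures are smaller (3 types, 120 genes) to keep the
whole suite fast.

## Known limitations

- No batch/platform correction between reference and ST data; if the
  assays differ strongly, predictions inherit the mismatch.
- The regularization strength λ_max is a user choice; there is no
  data-driven selection built in, and only a single smoothing round is
  applied (no iterative or Gaussian-process spatial models).
- HDF5 reading is eager; very large matrices should be subset upstream.
- Attribution explains the trained network, not the biology: genes a
  redundant model ignores receive low scores even if biologically
  informative (mitigated, not removed, by `input_dropout`).
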