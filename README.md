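# spotdeconv

Cell-type deconvolution of spatial transcriptomics (ST) data with a
neural network trained on simulated mixtures, plus k-nearest-neighbour
spatial regularization of the per-spot predictions.

## The problem

Most spot-based ST platforms (e.g. 10x Visium) do not reach single-cell
resolution: each spot captures transcripts from several cells. Given an
annotated scRNA-seq reference from the same biological context,
deconvolution estimates, for every spot, the fraction
p = (p_1, …, p_K) of each of K cell types contributing to its
expression. spotdeconv is aimed at computational biologists who have a
labelled reference and a gene × spot count matrix with coordinates, and
want fast per-spot composition estimates without hand-curated marker
signatures.

## The method

1. **Mixture simulation.** The reference is split into disjoint
   training/test cell subsets (stratified by type). Composition vectors
   are drawn from Dirichlet(α) with extra *pure* (one-hot) and *sparse*
   (random types zeroed) strata so the sampler covers the simplex
   interior, vertices and faces. Each pseudo-spot is the raw-count sum
   of n cells drawn within types by largest-remainder rounding of its
   composition.
2. **Network training.** Profiles are normalised (counts-per-10,000,
   log1p) and fed to a fully connected network (2 × 200 ReLU, dropout,
   softmax head) trained with KL divergence between true and predicted
   compositions, so every prediction lies on the probability simplex by
   construction. Held-out test mixtures give per-type PCC / CCC / RMSE
   and per-profile Jensen–Shannon divergence, showing whether each cell
   type is actually identifiable before touching real spots.
3. **Deconvolution + spatial regularization (optional).** The model
   predicts each spot's *intrinsic* composition from its own counts and
   an *extrinsic* composition from the summed counts of its k nearest
   neighbouring spots. The final estimate blends the two,
   `(1 − λ_i)·intrinsic + λ_i·extrinsic`, with
   λ_i = λ_max · (1 − d_i) gated by the transcriptional distance d_i
   between the spot and its neighbourhood — spots resembling their
   surroundings are smoothed, boundary spots are left alone.
4. **Interpretation & clustering.** Exact input gradients give per-gene
   attribution scores (gradient × input or integrated gradients) for
   each cell type, and spots can be k-means-clustered on their predicted
   compositions.

Everything is plain numpy/scipy/scikit-learn; the network is a compact
numpy implementation with explicit forward/backward passes, which keeps
runs deterministic for a fixed seed and makes exact input gradients
available for attribution.

## Worked example

```python
import spotdeconv as sd

cfg = sd.FixtureConfig(n_genes=200, n_types=4, n_cells_per_type=50,
                       marker_genes_per_type=15, grid=(8, 8), seed=0)
ref = sd.make_reference(cfg)                  # labelled scRNA-seq reference
st, true_props = sd.make_spatial(cfg, ref)    # 64 spots, known compositions

run = sd.deconvolute(ref, st, n_train_profiles=800, n_test_profiles=200,
                     n_cells_per_mixture=25, spatial_regularization=True,
                     seed=0)
print(run.report)
print(run.result.frame("regularized").head(3).round(3))
```

prints

```
              pcc     ccc    rmse
cell_type
ct00       0.9803  0.9611  0.0700
ct01       0.9775  0.9691  0.0640
ct02       0.9835  0.9668  0.0663
ct03       0.9805  0.9750  0.0590

overall: mean_pcc=0.9805, mean_ccc=0.9680, mean_rmse=0.0648, mean_jsd=0.0254
n_test_profiles: 200

               ct00   ct01   ct02   ct03
spot_000_000  0.444  0.034  0.466  0.056
spot_000_001  0.575  0.062  0.288  0.076
spot_000_002  0.430  0.044  0.487  0.039
```

The table reports, per cell type, the agreement between predicted and
true proportions across 200 held-out simulated mixtures (Pearson
correlation, Lin's concordance correlation, root mean squared error) —
a self-check that every type is identifiable from the reference. The
second table is the spatially regularized composition of the first
three spots; rows sum to 1.

The same workflow is available from the shell:

```sh
spotdeconv fixture demo/ --seed 0            # write a synthetic bundle
spotdeconv deconvolute --reference demo/reference \
    --cell-types demo/cell_types.csv --spatial demo/spatial \
    --coords demo/coords.csv --outdir out/ --spatial-regularization
spotdeconv interpret out/model --reference demo/reference \
    --cell-types demo/cell_types.csv --out out/gene_scores.csv
spotdeconv metrics demo/true_props.csv out/proportions_intrinsic.csv
spotdeconv cluster out/proportions_intrinsic.csv --n-clusters 2
```

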