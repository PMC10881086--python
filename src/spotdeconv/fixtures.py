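"""Synthetic datasets with known ground truth for testing and examples.

The generative model is a negative-binomial marker-block scheme: every
cell type owns a disjoint block of marker genes whose expected
expression is ``marker_fold_change`` times the gene's baseline rate;
all counts are overdispersed NB draws scaled by a per-cell library-size
factor. Ground truth — marker identity, cell labels, per-spot
compositions — is known by construction, which makes recovery and
attribution tests exact.

Three artefacts are generated:

* a labelled scRNA-seq reference (:func:`make_reference`);
* a lattice of multi-cell spots whose compositions follow per-region
  archetypes (:func:`make_spatial`), emulating spot-based platforms;
* a single-cell-resolution spatial dataset (:func:`make_single_cell_st`)
  that :func:`bin_single_cell_st` aggregates into square-bin pseudo-spots
  with exactly known compositions, the protocol used to score
  deconvolution quantitatively on imaging-based platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ReferenceDataset, SpatialDataset
from .simulate import synthesize_mixtures

__all__ = [
    "FixtureConfig",
    "SingleCellST",
    "make_reference",
    "make_spatial",
    "make_single_cell_st",
    "bin_single_cell_st",
]


@dataclass
class FixtureConfig:
    """Parameters of the synthetic generator.

    ``base_expression`` is the mean of the per-gene baseline NB rate;
    ``dispersion`` is the NB size parameter (smaller = more
    overdispersed); ``library_size_cv`` the coefficient of variation of
    the per-cell library factor. Marker blocks are disjoint across
    types. ``region_archetypes`` maps lattice regions (vertical bands by
    default) to composition archetypes; per-spot compositions are
    Dirichlet draws concentrated around the archetype.
    """

    n_genes: int = 500
    n_types: int = 5
    n_cells_per_type: int = 200
    marker_genes_per_type: int = 25
    marker_fold_change: float = 8.0
    base_expression: float = 2.0
    dispersion: float = 2.0
    library_size_cv: float = 0.2
    grid: tuple[int, int] = (10, 10)
    n_regions: int = 2
    region_archetypes: np.ndarray | None = None
    dirichlet_concentration: float = 15.0
    n_cells_per_spot: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.marker_genes_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.marker_fold_change <= 0:
            raise ValueError("marker_fold_change must be positive")
        if self.n_types < 2:
            raise ValueError("need >= 2 cell types")

    @property
    def cell_type_labels(self) -> list[str]:
        return [f"ct{t:02d}" for t in range(self.n_types)]

    def marker_block(self, type_index: int) -> np.ndarray:
        """Indices of the marker genes owned by one type."""
        m = self.marker_genes_per_type
        return np.arange(type_index * m, (type_index + 1) * m)

    def default_archetypes(self) -> np.ndarray:
        """One composition archetype per region.

        Regions favour complementary halves of the type set (with a
        small floor for every type) so neighbouring regions have clearly
        distinct but overlapping compositions.
        """
        if self.region_archetypes is not None:
            arch = np.asarray(self.region_archetypes, dtype=float)
            return arch / arch.sum(axis=1, keepdims=True)
        arch = np.full((self.n_regions, self.n_types), 0.05)
        for r in range(self.n_regions):
            favoured = np.arange(r, self.n_types, self.n_regions)
            arch[r, favoured] = 1.0
        return arch / arch.sum(axis=1, keepdims=True)


@dataclass
class SingleCellST:
    """Single-cell-resolution spatial data: counts + positions + labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    coords: np.ndarray
    labels: list[str]


def _nb_draw(rng, mean, size_param):
    """Negative-binomial counts with mean ``mean`` and size ``size_param``."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def make_reference(config: FixtureConfig) -> ReferenceDataset:
    """Generate the labelled scRNA-seq reference.

    For gene g in a cell of type t the count is negative binomial with
    mean ``base_expression * marker_fold_change**(g is a marker of t) *
    library_factor`` and size ``dispersion``; the per-cell library
    factor is lognormal with unit mean and CV ``library_size_cv``.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    G, T, C = config.n_genes, config.n_types, config.n_cells_per_type
    base = np.full(G, config.base_expression)
    cv = config.library_size_cv
    lib_sigma = np.sqrt(np.log1p(cv ** 2))
    gene_ids = [f"G{g:04d}" for g in range(G)]
    labels = config.cell_type_labels

    counts = np.zeros((G, T * C), dtype=np.int64)
    cell_types = []
    cell_ids = []
    col = 0
    for t in range(T):
        rate = base.copy()
        rate[config.marker_block(t)] *= config.marker_fold_change
        for c in range(C):
            lib = rng.lognormal(-lib_sigma ** 2 / 2, lib_sigma)
            counts[:, col] = _nb_draw(rng, rate * lib, config.dispersion)
            cell_ids.append(f"{labels[t]}_cell{c:04d}")
            cell_types.append(labels[t])
            col += 1
    return ReferenceDataset(counts=counts, gene_ids=gene_ids,
                            cell_ids=cell_ids, cell_types=cell_types)


def _draw_composition(rng, archetype, concentration):
    """Dirichlet draw concentrated around an archetype; zero entries of
    the archetype stay exactly zero (face of the simplex)."""
    archetype = np.asarray(archetype, dtype=float)
    support = archetype > 0
    out = np.zeros_like(archetype)
    if support.sum() == 1:
        out[support] = 1.0
        return out
    out[support] = rng.dirichlet(concentration * archetype[support])
    return out


def make_spatial(config: FixtureConfig, ref: ReferenceDataset):
    """Generate a lattice of multi-cell spots with known compositions.

    The grid is split into ``n_regions`` vertical bands; each spot's
    composition is a Dirichlet draw around its band's archetype, and its
    counts are synthesized exactly like training mixtures (cell draws
    from the reference, raw-count sums).

    Returns ``(SpatialDataset, true_props)`` where true_props rows
    follow the reference cell-type order.
    """
    rng = np.random.default_rng(config.seed + 101)
    rows, cols = config.grid
    arch = config.default_archetypes()
    n_regions = arch.shape[0]
    spot_ids, coords, regions = [], [], []
    for r in range(rows):
        for c in range(cols):
            spot_ids.append(f"spot_{r:03d}_{c:03d}")
            coords.append((float(c), float(r)))
            regions.append(min(c * n_regions // cols, n_regions - 1))
    n_spots = len(spot_ids)
    props = np.zeros((n_spots, config.n_types))
    for i in range(n_spots):
        props[i] = _draw_composition(rng, arch[regions[i]],
                                     config.dirichlet_concentration)
    mixtures = synthesize_mixtures(
        ref, list(ref.cell_ids), props, config.n_cells_per_spot,
        seed=config.seed + 202, partition="spatial")
    st = SpatialDataset(counts=mixtures.profiles, gene_ids=list(ref.gene_ids),
                        spot_ids=spot_ids, coords=np.asarray(coords))
    return st, mixtures.proportions


def make_single_cell_st(config: FixtureConfig, ref: ReferenceDataset,
                        n_cells: int = 2000) -> SingleCellST:
    """Scatter labelled single cells over the unit square.

    The square is split into ``n_regions`` vertical bands; a cell's type
    is drawn from its band's archetype and its counts are those of a
    randomly sampled reference cell of that type.
    """
    rng = np.random.default_rng(config.seed + 303)
    arch = config.default_archetypes()
    n_regions = arch.shape[0]
    xy = rng.random((n_cells, 2))
    types = ref.cell_type_order
    label_arr = np.asarray(ref.cell_types)
    per_type_cols = {t: np.flatnonzero(label_arr == t) for t in types}
    counts = np.zeros((len(ref.gene_ids), n_cells), dtype=np.int64)
    labels, cell_ids = [], []
    ref_counts = np.asarray(ref.counts)
    for i in range(n_cells):
        region = min(int(xy[i, 0] * n_regions), n_regions - 1)
        ti = rng.choice(len(types), p=arch[region])
        t = types[ti]
        src = rng.choice(per_type_cols[t])
        counts[:, i] = ref_counts[:, src]
        labels.append(t)
        cell_ids.append(f"cell{i:05d}")
    return SingleCellST(counts=counts, gene_ids=list(ref.gene_ids),
                        cell_ids=cell_ids, coords=xy, labels=labels)


def bin_single_cell_st(cells: SingleCellST, bin_size: float,
                       cell_type_order: list[str] | None = None):
    """Aggregate single cells into square-bin pseudo-spots.

    Spot counts are the exact sum of member-cell counts (total counts
    are conserved); true proportions are the member-type frequencies;
    the spot coordinate is the bin centre.

    Returns ``(SpatialDataset, true_props)``.
    """
    if len(cells.cell_ids) == 0:
        raise ValueError("no cells to bin")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if cell_type_order is None:
        cell_type_order = sorted(set(cells.labels))
    type_index = {t: i for i, t in enumerate(cell_type_order)}
    coords = np.asarray(cells.coords, dtype=float)
    ix = np.floor(coords[:, 0] / bin_size).astype(int)
    iy = np.floor(coords[:, 1] / bin_size).astype(int)
    bins: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(ix, iy)):
        bins.setdefault(key, []).append(i)
    keys = sorted(bins)
    counts = np.asarray(cells.counts)
    n_genes = counts.shape[0]
    spot_counts = np.zeros((n_genes, len(keys)), dtype=counts.dtype)
    props = np.zeros((len(keys), len(cell_type_order)))
    spot_ids, spot_coords = [], []
    for j, key in enumerate(keys):
        members = bins[key]
        spot_counts[:, j] = counts[:, members].sum(axis=1)
        for i in members:
            props[j, type_index[cells.labels[i]]] += 1
        props[j] /= len(members)
        spot_ids.append(f"bin_{key[0]}_{key[1]}")
        spot_coords.append(((key[0] + 0.5) * bin_size,
                            (key[1] + 0.5) * bin_size))
    st = SpatialDataset(counts=spot_counts, gene_ids=list(cells.gene_ids),
                        spot_ids=spot_ids, coords=np.asarray(spot_coords))
    return st, props
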