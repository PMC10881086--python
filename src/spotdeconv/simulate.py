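"""Simulation of mixed transcriptional profiles with known composition.

The reference is split into disjoint training and test cell subsets
(stratified by cell type). Proportion vectors are drawn from a Dirichlet
with two extra strata — pure (one-hot) profiles and sparse profiles with
a random subset of types zeroed — so the sampler covers the interior,
vertices and faces of the simplex. Each mixture is the raw-count sum of
cells drawn (with replacement, within type) according to a
largest-remainder rounding of its proportion vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ReferenceDataset

__all__ = [
    "ProportionSamplerConfig",
    "MixtureSet",
    "split_cells",
    "sample_proportions",
    "largest_remainder_counts",
    "synthesize_mixtures",
    "simulate_mixture_set",
]


@dataclass
class ProportionSamplerConfig:
    """Parameters of the composition sampler.

    ``frac_pure`` of the profiles are single-type (vertices of the
    simplex, cycling through the types); ``frac_sparse`` zero a random
    non-empty strict subset of types before the Dirichlet draw (faces);
    the rest are full Dirichlet(``dirichlet_alpha``) draws (interior).
    """

    n_profiles: int
    n_cells_per_mixture: int = 50
    dirichlet_alpha: float = 1.0
    frac_pure: float = 0.1
    frac_sparse: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_profiles <= 0:
            raise ValueError("n_profiles must be positive")
        if self.n_cells_per_mixture <= 0:
            raise ValueError("n_cells_per_mixture must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if not (0 <= self.frac_pure <= 1 and 0 <= self.frac_sparse <= 1):
            raise ValueError("frac_pure and frac_sparse must lie in [0, 1]")
        if self.frac_pure + self.frac_sparse > 1:
            raise ValueError("frac_pure + frac_sparse must be <= 1")


@dataclass
class MixtureSet:
    """Simulated mixtures: genes x n_profiles counts + true proportions."""

    profiles: np.ndarray
    proportions: np.ndarray
    cell_type_order: list[str]
    gene_ids: list[str]
    partition: str = "train"
    draw_lists: list[np.ndarray] | None = None

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape[1] != len(self.cell_type_order):
            raise ValueError("proportions columns must match cell_type_order")
        if self.profiles.shape[1] != self.proportions.shape[0]:
            raise ValueError("profiles columns must match proportion rows")
        rowsums = self.proportions.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise ValueError("every proportions row must sum to 1")

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[1]


def split_cells(ref: ReferenceDataset, test_frac: float, seed: int):
    """Stratified train/test split of reference cells.

    Every cell type contributes round(test_frac * n_type) cells to the
    test subset, clamped so both subsets keep at least one cell per
    type. Deterministic for a fixed seed.
    """
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(ref.cell_types)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for t in ref.cell_type_order:
        idx = np.flatnonzero(labels == t)
        if idx.size < 2:
            raise ValueError(
                f"cell type {t!r} has only {idx.size} cell(s); at least 2 "
                "are required to split into train and test")
        n_test = int(round(test_frac * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    cell_ids = np.asarray(ref.cell_ids)
    return (cell_ids[np.sort(train_idx)].tolist(),
            cell_ids[np.sort(test_idx)].tolist())


def sample_proportions(config: ProportionSamplerConfig,
                       n_types: int) -> np.ndarray:
    """Draw an n_profiles x n_types row-stochastic proportion matrix."""
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    rng = np.random.default_rng(config.seed)
    n = config.n_profiles
    n_pure = int(round(config.frac_pure * n))
    n_sparse = int(round(config.frac_sparse * n))
    n_sparse = min(n_sparse, n - n_pure)
    props = np.zeros((n, n_types))
    row = 0
    for i in range(n_pure):
        props[row, i % n_types] = 1.0
        row += 1
    for _ in range(n_sparse):
        # zero a uniformly chosen non-empty strict subset of types
        n_zero = rng.integers(1, n_types)
        zeroed = rng.choice(n_types, size=n_zero, replace=False)
        alive = np.setdiff1d(np.arange(n_types), zeroed)
        draw = rng.dirichlet(np.full(alive.size, config.dirichlet_alpha))
        props[row, alive] = draw
        row += 1
    n_full = n - row
    if n_full:
        props[row:] = rng.dirichlet(
            np.full(n_types, config.dirichlet_alpha), size=n_full)
    return props


def largest_remainder_counts(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer cell counts per type from a proportion vector.

    Floors ``proportions * total`` and hands the remaining units to the
    largest fractional remainders; remainder ties are broken by type
    order (lower index, i.e. lexicographically earlier label, first).
    """
    proportions = np.asarray(proportions, dtype=float)
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    shortfall = total - counts.sum()
    if shortfall > 0:
        remainders = raw - counts
        # stable sort on -remainder keeps index order within ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:shortfall]] += 1
    return counts


def synthesize_mixtures(ref: ReferenceDataset, cell_ids, proportions,
                        n_cells_per_mixture: int, seed: int,
                        partition: str = "train",
                        keep_draw_lists: bool = False) -> MixtureSet:
    """Build mixed count profiles from a cell subset and proportion rows.

    For each profile, the per-type cell counts are the largest-remainder
    rounding of proportion x n_cells_per_mixture; cells are drawn
    uniformly with replacement within type from ``cell_ids``; the
    profile is the element-wise sum of the drawn cells' raw counts. The
    stored proportions are the realised post-rounding fractions.
    """
    proportions = np.asarray(proportions, dtype=float)
    rng = np.random.default_rng(seed)
    types = ref.cell_type_order
    if proportions.shape[1] != len(types):
        raise ValueError("proportions columns must match reference cell types")

    id_to_col = {c: i for i, c in enumerate(ref.cell_ids)}
    subset_cols = np.asarray([id_to_col[c] for c in cell_ids])
    labels = np.asarray(ref.cell_types)
    per_type_cols = {}
    for t in types:
        cols = subset_cols[labels[subset_cols] == t]
        per_type_cols[t] = cols

    counts = np.asarray(ref.counts)
    n_genes = counts.shape[0]
    n_profiles = proportions.shape[0]
    profiles = np.zeros((n_genes, n_profiles), dtype=np.int64)
    realized = np.zeros_like(proportions)
    draw_lists: list[np.ndarray] = []

    for j in range(n_profiles):
        ncells = largest_remainder_counts(proportions[j], n_cells_per_mixture)
        drawn_cols = []
        for ti, t in enumerate(types):
            if ncells[ti] == 0:
                continue
            pool = per_type_cols[t]
            if pool.size == 0:
                raise ValueError(
                    f"cell type {t!r} has positive proportion but no cells "
                    f"in the {partition!r} subset")
            drawn_cols.append(rng.choice(pool, size=ncells[ti], replace=True))
        drawn_cols = np.concatenate(drawn_cols)
        profiles[:, j] = counts[:, drawn_cols].sum(axis=1)
        realized[j] = ncells / n_cells_per_mixture
        if keep_draw_lists:
            draw_lists.append(drawn_cols)

    return MixtureSet(profiles=profiles, proportions=realized,
                      cell_type_order=list(types), gene_ids=list(ref.gene_ids),
                      partition=partition,
                      draw_lists=draw_lists if keep_draw_lists else None)


def simulate_mixture_set(ref: ReferenceDataset, cell_ids,
                         config: ProportionSamplerConfig,
                         partition: str = "train") -> MixtureSet:
    """Sample proportions and synthesize the matching mixtures in one call."""
    props = sample_proportions(config, n_types=len(ref.cell_type_order))
    return synthesize_mixtures(ref, cell_ids, props,
                               config.n_cells_per_mixture,
                               seed=config.seed + 1, partition=partition)
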