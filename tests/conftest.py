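"""Shared fixtures: small synthetic datasets and a trained model.

Everything is generated programmatically; session scope keeps the
(seconds-long) network trainings to a minimum across the suite.
"""

import numpy as np
import pytest

import spotdeconv as sd


@pytest.fixture(scope="session")
def small_config():
    # 3 well-separated types, small enough to train in a couple of seconds
    return sd.FixtureConfig(n_genes=120, n_types=3, n_cells_per_type=40,
                            marker_genes_per_type=10, marker_fold_change=8.0,
                            grid=(8, 8), seed=7)


@pytest.fixture(scope="session")
def small_ref(small_config):
    return sd.make_reference(small_config)


@pytest.fixture(scope="session")
def small_split(small_ref):
    return sd.split_cells(small_ref, test_frac=0.2, seed=7)


@pytest.fixture(scope="session")
def norm_spec(small_ref):
    return sd.NormalizationSpec(gene_space=sorted(small_ref.gene_ids))


@pytest.fixture(scope="session")
def train_mixtures(small_ref, small_split):
    cfg = sd.ProportionSamplerConfig(n_profiles=600, n_cells_per_mixture=25,
                                     seed=11)
    return sd.simulate_mixture_set(small_ref, small_split[0], cfg, "train")


@pytest.fixture(scope="session")
def test_mixtures(small_ref, small_split):
    cfg = sd.ProportionSamplerConfig(n_profiles=150, n_cells_per_mixture=25,
                                     seed=13)
    return sd.simulate_mixture_set(small_ref, small_split[1], cfg, "test")


@pytest.fixture(scope="session")
def trained_model(train_mixtures, norm_spec):
    config = sd.ModelConfig(hidden_sizes=(64, 64), max_epochs=40, seed=7)
    return sd.train(train_mixtures, norm_spec, config)


@pytest.fixture(scope="session")
def interpret_model(small_ref, small_split, norm_spec):
    """Model trained with gene dropout, the interpretation-oriented setting
    that spreads weight across redundant markers. Needs enough mixtures to
    be well calibrated, or attribution reflects a poor model."""
    cfg = sd.ProportionSamplerConfig(n_profiles=1500, n_cells_per_mixture=25,
                                     seed=11)
    mixtures = sd.simulate_mixture_set(small_ref, small_split[0], cfg, "train")
    config = sd.ModelConfig(input_dropout=0.1, seed=7)
    return sd.train(mixtures, norm_spec, config)


@pytest.fixture(scope="session")
def two_region_spatial(small_config, small_ref):
    """Lattice with two composition regions and its ground truth."""
    return sd.make_spatial(small_config, small_ref)
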