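"""End-to-end orchestration: reference + spatial data in, compositions out.

The pipeline follows the method's four steps: simulate mixtures with
known composition from the reference, train and evaluate the network,
deconvolute the spots' intrinsic profiles, and (optionally) spatially
regularize against extrinsic neighbourhood profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import (NormalizationSpec, ReferenceDataset, SpatialDataset,
                       harmonize_gene_space)
from .network import (DeconvolutionModel, EvaluationReport, ModelConfig,
                      evaluate, train)
from .simulate import (MixtureSet, ProportionSamplerConfig, simulate_mixture_set,
                       split_cells)
from .spatial import (DeconvResult, RegularizationConfig, build_extrinsic_profiles,
                      build_spatial_graph, regularize)

logger = logging.getLogger("spotdeconv")

__all__ = ["DeconvolutionRun", "deconvolute"]


@dataclass
class DeconvolutionRun:
    """Everything a deconvolution run produced, kept for inspection."""

    model: DeconvolutionModel
    report: EvaluationReport
    train_set: MixtureSet
    test_set: MixtureSet
    result: DeconvResult
    norm_spec: NormalizationSpec


def deconvolute(ref: ReferenceDataset, st: SpatialDataset,
                n_train_profiles: int = 2000, n_test_profiles: int = 500,
                n_cells_per_mixture: int = 50, test_cell_frac: float = 0.2,
                model_config: ModelConfig | None = None,
                sampler_alpha: float = 1.0, frac_pure: float = 0.1,
                frac_sparse: float = 0.3,
                min_counts: int = 1, min_cells_frac: float = 0.0,
                spatial_regularization: bool = False, k_neighbors: int = 6,
                reg_config: RegularizationConfig | None = None,
                seed: int = 0) -> DeconvolutionRun:
    """Run the full workflow and return all intermediates.

    With ``spatial_regularization=False`` the result's regularized
    proportions are identical to the intrinsic ones.
    """
    model_config = model_config or ModelConfig(seed=seed)
    norm_spec = harmonize_gene_space(ref, st, min_counts=min_counts,
                                     min_cells_frac=min_cells_frac)
    logger.info("gene space: %d genes", len(norm_spec.gene_space))

    train_ids, test_ids = split_cells(ref, test_frac=test_cell_frac, seed=seed)
    train_cfg = ProportionSamplerConfig(
        n_profiles=n_train_profiles, n_cells_per_mixture=n_cells_per_mixture,
        dirichlet_alpha=sampler_alpha, frac_pure=frac_pure,
        frac_sparse=frac_sparse, seed=seed + 11)
    test_cfg = ProportionSamplerConfig(
        n_profiles=n_test_profiles, n_cells_per_mixture=n_cells_per_mixture,
        dirichlet_alpha=sampler_alpha, frac_pure=frac_pure,
        frac_sparse=frac_sparse, seed=seed + 23)
    train_set = simulate_mixture_set(ref, train_ids, train_cfg, "train")
    test_set = simulate_mixture_set(ref, test_ids, test_cfg, "test")
    logger.info("simulated %d train / %d test mixtures",
                train_set.n_profiles, test_set.n_profiles)

    model = train(train_set, norm_spec, model_config)
    report = evaluate(model, test_set)
    logger.info("test mean PCC %.3f, mean CCC %.3f",
                report.overall["mean_pcc"], report.overall["mean_ccc"])

    st_input = model.prepare(st.counts, st.gene_ids)
    intrinsic = model.net.predict(st_input)

    if spatial_regularization:
        graph = build_spatial_graph(st, k=k_neighbors)
        ext_counts = build_extrinsic_profiles(st, graph)
        ext_input = model.prepare(ext_counts, st.gene_ids)
        extrinsic = model.net.predict(ext_input)
        result = regularize(intrinsic, extrinsic, st_input, ext_input,
                            config=reg_config or RegularizationConfig(),
                            spot_ids=st.spot_ids,
                            cell_type_order=model.cell_type_order)
    else:
        result = regularize(intrinsic, intrinsic.copy(), st_input, st_input,
                            config=RegularizationConfig(lambda_max=0.0),
                            spot_ids=st.spot_ids,
                            cell_type_order=model.cell_type_order)

    return DeconvolutionRun(model=model, report=report, train_set=train_set,
                            test_set=test_set, result=result,
                            norm_spec=norm_spec)
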