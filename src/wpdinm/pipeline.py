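"""End-to-end pipeline: weighted networks -> initial scores -> ranking.

`run_pipeline` executes the full method in order: weighted PPI matrix,
weighted DDI matrix, heterogeneous PDI block matrix, allocation matrix and
initial scores, weight-allocation matrix, damped iteration to the fixed
point, and the final deterministic ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import InputBundle
from .domain_weighting import (
    WeightedDDIMatrix,
    WeightedPDIMatrix,
    build_weighted_ddi,
    build_weighted_pdi,
)
from .initial_scoring import (
    AllocationProbabilityMatrix,
    FeatureScores,
    allocation_matrix,
    combine_features,
    domain_derived_scores,
    initial_score_vector,
    orthology_feature,
    subcellular_feature,
    triangle_feature,
)
from .ppi_weighting import WeightedPPIMatrix, build_weighted_ppi
from .rank_engine import (
    RankedList,
    ScoreVector,
    WeightAllocationMatrix,
    iterate_scores,
    rank_proteins,
    weight_allocation_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    bundle: InputBundle
    wppi: WeightedPPIMatrix
    wddi: WeightedDDIMatrix | None
    wpdi: WeightedPDIMatrix | None
    apm: AllocationProbabilityMatrix | None
    features: FeatureScores
    s0: np.ndarray
    scores: ScoreVector
    ranking: RankedList


def run_pipeline(bundle: InputBundle) -> PipelineResult:
    cfg = bundle.config
    net = bundle.network
    o = net.n_proteins
    logger.info("network: %d proteins, %d edges", o, net.n_edges)

    wppi = build_weighted_ppi(net, bundle.expression, cfg)
    logger.info("weighted PPI matrix built (%d expressed proteins)",
                len(bundle.expression.coverage & set(net.protein_ids)))

    q = bundle.domains.n_domains
    if q > 0:
        wddi = build_weighted_ddi(bundle.domains, delta_prime=cfg.delta_prime)
        wpdi = build_weighted_pdi(wppi, wddi, bundle.domains)
        apm = allocation_matrix(wpdi, bundle.domains)
        psd = domain_derived_scores(apm)
        logger.info("heterogeneous PDI matrix: %d protein + %d domain nodes", o, q)
    else:
        wddi = wpdi = apm = None
        psd = np.zeros(o)
        logger.warning("no domains; domain-derived scores are all 0")

    fs_sl = subcellular_feature(bundle.subcellular, net.protein_ids)
    fs_tri = triangle_feature(net)
    fs_ort = orthology_feature(bundle.orthology, net.protein_ids)
    fs = combine_features(fs_sl, fs_tri, fs_ort, cfg)
    features = FeatureScores(psd=psd, fs_sl=fs_sl, fs_tri=fs_tri,
                             fs_ort=fs_ort, combined=fs)
    s0 = initial_score_vector(psd, fs, cfg)

    wapm = weight_allocation_matrix(wppi, rho=cfg.rho,
                                    protein_ids=net.protein_ids)
    scores = iterate_scores(wapm, s0, mu=cfg.mu, epsilon=cfg.epsilon,
                            max_iter=cfg.max_iter)
    logger.info("converged after %d iterations (residual^2 = %.3e)",
                scores.iterations, scores.residual_sq)

    ranking = rank_proteins(scores.values, net.protein_ids)
    return PipelineResult(
        bundle=bundle, wppi=wppi, wddi=wddi, wpdi=wpdi, apm=apm,
        features=features, s0=s0, scores=scores, ranking=ranking,
    )
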