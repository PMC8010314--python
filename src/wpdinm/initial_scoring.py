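"""Initial protein scores: domain allocation plus three feature channels.

Each domain carries one unit of score and distributes it over its member
proteins in proportion to the heterogeneous protein-domain weights (the
allocation probability matrix); the resulting per-protein PSD vector
conserves total mass Q.  Three further channels score each protein directly:

* subcellular localisation — compartments scored by their size relative to
  the mean compartment size, a protein summing the scores of its
  compartments;
* triangles — the mean, over a protein's neighbours, of (shared neighbours
  + 1), normalised by the network-wide maximum;
* orthology — the protein's ortholog count normalised by the maximum.

The combined feature score is phi*FS_SL + theta*FS_TRI + tau*FS_ORT and the
initial score S0 = omega*PSD + (1-omega)*FS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .datatypes import (
    DomainAnnotation,
    OrthologyScores,
    ProteinNetwork,
    SubcellularAnnotation,
)
from .domain_weighting import WeightedPDIMatrix
from .errors import WpdinmError


@dataclass
class AllocationProbabilityMatrix:
    """Q x O row-stochastic matrix distributing domain score to members."""

    matrix: np.ndarray


@dataclass
class FeatureScores:
    """Per-protein feature vectors, aligned to the bundle's protein order."""

    psd: np.ndarray
    fs_sl: np.ndarray
    fs_tri: np.ndarray
    fs_ort: np.ndarray
    combined: np.ndarray


def allocation_matrix(
    wpdi: WeightedPDIMatrix, domains: DomainAnnotation
) -> AllocationProbabilityMatrix:
    """Row-normalise the domain->protein weights over member proteins.

    A domain whose member weights are all zero allocates uniformly over its
    members so its unit of score is not lost.
    """
    member = domains.matrix.astype(bool)  # O x Q
    if member.shape[1] and not member.any(axis=0).all():
        raise WpdinmError("a domain has no member proteins")
    weights = np.where(member, wpdi.pd_block, 0.0).T  # Q x O
    row_sum = weights.sum(axis=1)
    apm = np.zeros_like(weights)
    nz = row_sum > 0
    apm[nz] = weights[nz] / row_sum[nz, None]
    for j in np.nonzero(~nz)[0]:
        members = member[:, j]
        apm[j, members] = 1.0 / members.sum()
    return AllocationProbabilityMatrix(matrix=apm)


def domain_derived_scores(apm: AllocationProbabilityMatrix) -> np.ndarray:
    """PSD = APM^T . 1_Q, i.e. the column sums; total mass equals Q."""
    return apm.matrix.sum(axis=0)


def subcellular_feature(
    annotation: SubcellularAnnotation, protein_ids: list[str]
) -> np.ndarray:
    n = len(protein_ids)
    if annotation.n_localizations == 0:
        return np.zeros(n)
    counts = annotation.counts
    s_avg = sum(counts.values()) / annotation.n_localizations
    if s_avg == 0:
        return np.zeros(n)
    s_sl = {loc: c / s_avg for loc, c in counts.items()}
    out = np.zeros(n)
    for i, pid in enumerate(protein_ids):
        out[i] = sum(s_sl[loc] for loc in annotation.membership.get(pid, ()))
    return out


def triangle_feature(network: ProteinNetwork) -> np.ndarray:
    """Mean per-neighbour triangle support, max-normalised; isolated -> 0."""
    a = network.adjacency.astype(float)
    deg = a.sum(axis=1)
    common = a @ a
    tri = ((common + 1.0) * a).sum(axis=1)  # sum over neighbours only
    avg = np.zeros_like(tri)
    nz = deg > 0
    avg[nz] = tri[nz] / deg[nz]
    top = avg.max(initial=0.0)
    return avg / top if top > 0 else avg


def orthology_feature(
    orthology: OrthologyScores, protein_ids: list[str]
) -> np.ndarray:
    f = np.array([orthology.get(p) for p in protein_ids], dtype=float)
    top = f.max(initial=0.0)
    return f / top if top > 0 else f


def combine_features(
    fs_sl: np.ndarray,
    fs_tri: np.ndarray,
    fs_ort: np.ndarray,
    config: PipelineConfig,
) -> np.ndarray:
    phi, theta, tau = config.feature_weights()
    return phi * fs_sl + theta * fs_tri + tau * fs_ort


def initial_score_vector(
    psd: np.ndarray, combined_features: np.ndarray, config: PipelineConfig
) -> np.ndarray:
    """S0 = omega * PSD + (1 - omega) * FS."""
    if psd.shape != combined_features.shape:
        raise WpdinmError("PSD and feature vectors differ in length")
    return config.omega * psd + (1.0 - config.omega) * combined_features
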