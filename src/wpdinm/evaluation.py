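"""Evaluation of essential-protein rankings.

Implements the standard protocol for this problem: hit counts among the top
k% of the ranking (k computed with the ceiling convention), cumulative-hit
("jackknife") curves, ROC and precision-recall curves with trapezoidal
areas, overlap tables between two rankings, and five classical centrality
baselines (degree, betweenness, closeness, eigenvector, and the
edge-clustering-coefficient neighbour centrality NC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn import metrics as _skm

from .datatypes import EssentialSet, ProteinNetwork
from .errors import WpdinmError
from .rank_engine import RankedList

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25)

BASELINES = ("DC", "BC", "CC", "EC", "NC")


@dataclass
class TopKRow:
    fraction: float
    k: int
    hits: int

    @property
    def hit_rate(self) -> float:
        return self.hits / self.k if self.k else 0.0


@dataclass
class ROCPRResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc_roc: float
    precision: np.ndarray
    recall: np.ndarray
    auc_pr: float


def top_candidates(n_proteins: int, fraction: float) -> int:
    """Number of candidates at a top-k% cutoff: ceil(fraction * O)."""
    if not 0.0 < fraction <= 1.0:
        raise WpdinmError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n_proteins)


def top_fraction_hits(
    ranking: RankedList,
    essentials: EssentialSet,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> list[TopKRow]:
    if not ranking:
        raise WpdinmError("empty ranking")
    n = len(ranking)
    rows = []
    for f in fractions:
        k = top_candidates(n, f)
        hits = sum(1 for pid, _ in ranking[:k] if pid in essentials)
        rows.append(TopKRow(fraction=f, k=k, hits=hits))
    return rows


def jackknife_curve(
    ranking: RankedList, essentials: EssentialSet, n_top: int
) -> np.ndarray:
    """Cumulative count of essentials among the top-x ranks, x = 1..n_top."""
    if n_top > len(ranking):
        raise WpdinmError("n_top exceeds ranking length")
    flags = np.array([pid in essentials for pid, _ in ranking[:n_top]], dtype=int)
    return np.cumsum(flags)


def roc_pr_auc(
    ids: list[str], scores: np.ndarray, essentials: EssentialSet
) -> ROCPRResult:
    """ROC/PR curves and trapezoidal areas; ties get half credit in the AUC."""
    y = np.array([pid in essentials for pid in ids], dtype=int)
    if y.all() or not y.any():
        raise WpdinmError("need at least one essential and one non-essential")
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = _skm.roc_curve(y, s)
    auc_roc = float(_skm.roc_auc_score(y, s))
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    auc_pr = float(_skm.auc(recall, precision))
    return ROCPRResult(fpr=fpr, tpr=tpr, auc_roc=auc_roc,
                       precision=precision, recall=recall, auc_pr=auc_pr)


def _neighbor_centrality(network: ProteinNetwork) -> np.ndarray:
    """NC: per protein, the sum of edge clustering coefficients of its edges.

    ECC(u, v) = |N(u) & N(v)| / min(deg(u) - 1, deg(v) - 1), 0 when the
    denominator is 0.
    """
    a = network.adjacency.astype(float)
    deg = a.sum(axis=1)
    common = a @ a
    denom = np.minimum.outer(deg - 1.0, deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.where((a == 1.0) & (denom > 0), common / denom, 0.0)
    return ecc.sum(axis=1)


def baseline_centralities(network: ProteinNetwork, method: str) -> np.ndarray:
    """Classical centrality scores aligned to the network's protein order.

    DC is the raw degree; BC/CC use networkx defaults (CC normalises within
    the reachable component); EC is computed on the largest connected
    component and 0 elsewhere; NC sums edge clustering coefficients.
    """
    method = method.upper()
    if method not in BASELINES:
        raise WpdinmError(f"unknown baseline {method!r}; pick one of {BASELINES}")
    if method == "NC":
        return _neighbor_centrality(network)
    g = nx.Graph()
    g.add_nodes_from(network.protein_ids)
    ii, jj = np.nonzero(np.triu(network.adjacency, 1))
    g.add_edges_from(
        (network.protein_ids[i], network.protein_ids[j]) for i, j in zip(ii, jj)
    )
    if method == "DC":
        values = {p: float(d) for p, d in g.degree()}
    elif method == "BC":
        values = nx.betweenness_centrality(g)
    elif method == "CC":
        values = nx.closeness_centrality(g)
    else:  # EC on the largest component, 0 elsewhere
        values = {p: 0.0 for p in network.protein_ids}
        if g.number_of_edges() > 0:
            giant = max(nx.connected_components(g), key=len)
            values.update(nx.eigenvector_centrality_numpy(g.subgraph(giant)))
    return np.array([values[p] for p in network.protein_ids])


def overlap_report(
    ranking_a: RankedList,
    ranking_b: RankedList,
    cutoff: int,
    essentials: EssentialSet | None = None,
) -> dict:
    """Top-``cutoff`` set overlap between two rankings.

    Reports |A & B|, |A - B|, |B - A| and, when a gold standard is given,
    the essential fraction within each difference set.
    """
    top_a = {pid for pid, _ in ranking_a[:cutoff]}
    top_b = {pid for pid, _ in ranking_b[:cutoff]}
    a_only = top_a - top_b
    b_only = top_b - top_a
    out = {
        "cutoff": cutoff,
        "common": len(top_a & top_b),
        "a_only": len(a_only),
        "b_only": len(b_only),
    }
    if essentials is not None:
        out["a_only_essential_pct"] = (
            100.0 * sum(p in essentials for p in a_only) / len(a_only)
            if a_only else 0.0
        )
        out["b_only_essential_pct"] = (
            100.0 * sum(p in essentials for p in b_only) / len(b_only)
            if b_only else 0.0
        )
    return out
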