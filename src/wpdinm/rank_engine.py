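"""Damped iterative ranking on the weighted PPI network.

Score mass flows between proteins through their strongest shared neighbour:
for an ordered pair (i, j) with at least one common neighbour in the
weighted network, the allocation weight is WppiM(i, k*) * WppiM(k*, j) where
k* is the common neighbour with the largest weight to j (ties broken by
ascending protein id).  Rows with any mass are rescaled to sum exactly rho,
giving a substochastic matrix, so the PageRank-style update

    S_{t+1} = mu * WAPM . S_t + (1 - mu) * S0

is a contraction with factor mu * rho < 1 and converges to the unique fixed
point of (I - mu*WAPM) S = (1 - mu) S0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ConvergenceError
from .ppi_weighting import WeightedPPIMatrix


@dataclass
class WeightAllocationMatrix:
    """O x O directed allocation matrix; row sums are rho or exactly 0."""

    matrix: np.ndarray
    rho: float


@dataclass
class ScoreVector:
    values: np.ndarray
    iterations: int
    converged: bool
    residual_sq: float


RankedList = list[tuple[str, float]]


def weight_allocation_matrix(
    wppi: WeightedPPIMatrix,
    rho: float = 0.85,
    protein_ids: list[str] | None = None,
) -> WeightAllocationMatrix:
    """Build the strongest-shared-neighbour allocation matrix.

    Neighbourhoods are taken in the weighted network (nonzero entries).
    Ordered pairs without a common neighbour stay 0; nonzero rows are
    normalised to sum rho.
    """
    if not 0.0 < rho <= 1.0:
        raise ConfigError(f"rho must be in (0, 1], got {rho}")
    w = wppi.matrix
    n = w.shape[0]
    ids = protein_ids if protein_ids is not None else [str(i) for i in range(n)]
    adjacent = w > 0  # zero diagonal keeps self out of neighbourhoods
    m = np.zeros((n, n))
    rows = np.arange(n)
    for j in range(n):
        nb = np.nonzero(adjacent[:, j])[0]
        if nb.size == 0:
            continue
        # neighbours of j, strongest weight to j first; ties by ascending id
        order = np.array(sorted(nb, key=lambda k: (-w[k, j], ids[k])))
        sub = adjacent[:, order]  # n x T membership of each i's neighbourhood
        has_common = sub.any(axis=1)
        k_star = order[sub.argmax(axis=1)]
        col = np.where(has_common, w[rows, k_star] * w[k_star, j], 0.0)
        col[j] = 0.0
        m[:, j] = col
    row_sum = m.sum(axis=1)
    nz = row_sum > 0
    m[nz] *= rho / row_sum[nz, None]
    return WeightAllocationMatrix(matrix=m, rho=rho)


def iterate_scores(
    wapm: WeightAllocationMatrix,
    s0: np.ndarray,
    mu: float = 0.4,
    epsilon: float = 1e-6,
    max_iter: int = 10_000,
) -> ScoreVector:
    """Iterate S_{t+1} = mu*WAPM.S_t + (1-mu)*S0 until ||dS||^2 < epsilon."""
    if not 0.0 < mu < 1.0:
        raise ConfigError(f"mu must be in (0, 1), got {mu}")
    if epsilon <= 0:
        raise ConfigError("epsilon must be > 0")
    s0 = np.asarray(s0, dtype=float)
    if s0.shape[0] != wapm.matrix.shape[0]:
        raise ConfigError("score vector length does not match matrix size")
    s = s0.copy()
    restart = (1.0 - mu) * s0
    residual_sq = np.inf
    for it in range(1, max_iter + 1):
        s_next = mu * (wapm.matrix @ s) + restart
        diff = s_next - s
        residual_sq = float(diff @ diff)
        s = s_next
        if residual_sq < epsilon:
            return ScoreVector(values=s, iterations=it, converged=True,
                               residual_sq=residual_sq)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations "
        f"(residual^2 = {residual_sq:.3e})",
        residual_sq=residual_sq,
    )


def rank_proteins(scores: np.ndarray, ids: list[str]) -> RankedList:
    """Descending by score, ties by ascending protein id; deterministic."""
    if len(scores) != len(ids):
        raise ConfigError("scores and ids differ in length")
    order = sorted(range(len(ids)), key=lambda i: (-float(scores[i]), ids[i]))
    return [(ids[i], float(scores[i])) for i in order]
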