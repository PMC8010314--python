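"""Weighted DDI construction and assembly of the heterogeneous PDI matrix.

Domain-domain similarity is a Gaussian interaction-profile kernel over the
columns of the binary protein-domain membership matrix: two domains are
similar when they annotate similar protein sets.  The heterogeneous
protein-domain matrix is a symmetric (O+Q) x (O+Q) block matrix whose PP
block is the weighted PPI matrix, DD block the weighted DDI matrix, and PD
block the average of two directed propagations: protein-side (PPI-weighted
mean of neighbours' domain membership) and domain-side (DDI-weighted mean of
the protein's annotated domains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import DomainAnnotation
from .errors import DegenerateInputError, DimensionError, EmptyInputError
from .ppi_weighting import WeightedPPIMatrix


@dataclass
class WeightedDDIMatrix:
    matrix: np.ndarray  # Q x Q, symmetric, unit diagonal, entries in (0, 1]
    bandwidth: float


@dataclass
class WeightedPDIMatrix:
    """(O+Q) x (O+Q) block matrix over protein then domain nodes."""

    matrix: np.ndarray
    n_proteins: int
    n_domains: int

    @property
    def pp(self) -> np.ndarray:
        o = self.n_proteins
        return self.matrix[:o, :o]

    @property
    def dd(self) -> np.ndarray:
        o = self.n_proteins
        return self.matrix[o:, o:]

    @property
    def pd_block(self) -> np.ndarray:
        """O x Q protein-domain block."""
        o = self.n_proteins
        return self.matrix[:o, o:]


def build_weighted_ddi(
    domains: DomainAnnotation, delta_prime: float = 1.0
) -> WeightedDDIMatrix:
    """Gaussian kernel over domain annotation profiles (matrix columns).

    delta = delta_prime / mean_k ||IP(d_k)||^2 with IP(d_k) the k-th column
    of the membership matrix.
    """
    q = domains.n_domains
    if q == 0:
        raise EmptyInputError("no domains; cannot build a DDI matrix")
    profiles = domains.matrix.astype(float).T  # Q x O, row = domain profile
    mean_sq = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise DegenerateInputError("all domain profiles empty")
    delta = delta_prime / mean_sq
    sqd = squareform(pdist(profiles, metric="sqeuclidean")) if q > 1 else np.zeros((1, 1))
    return WeightedDDIMatrix(matrix=np.exp(-delta * sqd), bandwidth=delta)


def build_weighted_pdi(
    wppi: WeightedPPIMatrix,
    wddi: WeightedDDIMatrix,
    domains: DomainAnnotation,
) -> WeightedPDIMatrix:
    """Assemble the symmetric heterogeneous protein-domain matrix.

    The PD block averages the protein-side propagation (row-normalised by
    the protein's total PPI weight; 0 when that weight is 0) with the
    domain-side propagation (column-normalised by the DDI column sum, which
    is always >= 1 thanks to the unit diagonal).
    """
    wp = wppi.matrix
    wd = wddi.matrix
    o = wp.shape[0]
    q = wd.shape[0]
    if domains.matrix.shape != (o, q):
        raise DimensionError(
            f"membership matrix is {domains.matrix.shape}, expected {(o, q)}"
        )
    opdi = domains.matrix.astype(float)

    row_mass = wp.sum(axis=1)
    wpd = np.zeros((o, q))
    nz = row_mass > 0
    wpd[nz] = (wp[nz] @ opdi) / row_mass[nz, None]

    col_mass = wd.sum(axis=0)  # >= 1 (unit diagonal)
    wdp = (opdi @ wd) / col_mass[None, :]

    pd_block = (wpd + wdp) / 2.0
    block = np.block([[wp, pd_block], [pd_block.T, wd]])
    return WeightedPDIMatrix(matrix=block, n_proteins=o, n_domains=q)
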