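"""Weighted PPI network construction.

Edge weights fuse two similarity channels:

* an expression channel — each protein's gene-expression time series is
  mapped to a frequency-magnitude spectrum with the discrete Fourier
  transform, and pairs are compared with a Gaussian interaction-profile
  kernel GK whose bandwidth is normalised by the mean squared spectrum norm;
* a topology channel — TFP, a common-neighbour ratio computed from the
  binary network.

For an interacting pair the weight is ``beta * PA + (1 - beta)`` where PA is
GK when both proteins are expressed and TFP otherwise.  Non-interacting
pairs that share at least one neighbour and are both expressed get the
product ``TFP * GK``; all remaining non-edges are 0, which keeps the matrix
supported on the 2-hop neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import PipelineConfig
from .datatypes import ExpressionTable, ProteinNetwork
from .errors import DegenerateInputError, DimensionError, WpdinmError


@dataclass
class SpectrumTable:
    """DFT magnitude spectra for every expressed protein."""

    dft_length: int
    magnitudes: dict[str, np.ndarray]


@dataclass
class GaussianKernel:
    """Pairwise GK values over the expressed proteins."""

    proteins: list[str]
    alpha: float
    matrix: np.ndarray  # |P| x |P|, symmetric, unit diagonal

    def value(self, a: str, b: str) -> float:
        idx = {p: i for i, p in enumerate(self.proteins)}
        return float(self.matrix[idx[a], idx[b]])


@dataclass
class WeightedPPIMatrix:
    matrix: np.ndarray  # O x O, symmetric, zero diagonal, nonnegative
    bandwidth: float | None  # kernel alpha, None when nothing was expressed


def dft_spectrum(series, n_points: int | None = None) -> np.ndarray:
    """Magnitude spectrum |sum_{y=1..M} x_y exp(-i 2 pi t y / M)|, t=0..N-1.

    The exponent base stays M even when N > M, so components beyond the
    series length repeat the length-M spectrum periodically.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise DimensionError("series must be a nonempty 1-D vector")
    m = x.size
    n = m if n_points is None else int(n_points)
    if n < m:
        raise WpdinmError(f"dft length N={n} must be >= series length M={m}")
    t = np.arange(n)[:, None]
    y = np.arange(1, m + 1)[None, :]
    phases = np.exp(-2j * np.pi * t * y / m)
    return np.abs(phases @ x)


def compute_spectra(
    expression: ExpressionTable, n_points: int | None = None
) -> SpectrumTable:
    n = expression.series_length if n_points is None else n_points
    mags = {
        p: dft_spectrum(v, n_points=n) for p, v in expression.profiles.items()
    }
    return SpectrumTable(dft_length=n, magnitudes=mags)


def gk_matrix(spectra: SpectrumTable, alpha_prime: float = 1.0) -> GaussianKernel:
    """Gaussian interaction-profile kernel over expressed proteins.

    alpha = alpha_prime / mean_k ||DF(p_k)||^2; GK(i,j) = exp(-alpha *
    ||DF(p_i) - DF(p_j)||^2).
    """
    if not spectra.magnitudes:
        raise DegenerateInputError("no spectra to build a kernel from")
    proteins = list(spectra.magnitudes)
    mat = np.vstack([spectra.magnitudes[p] for p in proteins])
    mean_sq = float((mat ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise DegenerateInputError("all spectra are zero; kernel bandwidth undefined")
    alpha = alpha_prime / mean_sq
    sqd = squareform(pdist(mat, metric="sqeuclidean"))
    return GaussianKernel(proteins=proteins, alpha=alpha,
                          matrix=np.exp(-alpha * sqd))


def tfp_score(network: ProteinNetwork, i: int, j: int) -> float:
    """Topology similarity (|common| + 1) / ((deg_i + 1) * (deg_j + 1))."""
    if i == j:
        raise WpdinmError("tfp_score is undefined for a protein with itself")
    a = network.adjacency
    common = int((a[i] & a[j]).sum())
    return (common + 1) / ((int(a[i].sum()) + 1) * (int(a[j].sum()) + 1))


def build_weighted_ppi(
    network: ProteinNetwork,
    expression: ExpressionTable,
    config: PipelineConfig | None = None,
) -> WeightedPPIMatrix:
    config = config or PipelineConfig()
    beta = config.beta
    a = network.adjacency.astype(float)
    n = network.n_proteins
    if n == 0:
        raise WpdinmError("empty network")
    deg = a.sum(axis=1)
    common = a @ a
    tfp = (common + 1.0) / np.outer(deg + 1.0, deg + 1.0)

    has_expr = np.zeros(n, dtype=bool)
    gk_full = np.zeros((n, n))
    alpha: float | None = None
    usable = {p for p in expression.coverage if p in network.index}
    if usable:
        sub = ExpressionTable(
            series_length=expression.series_length,
            profiles={p: expression.profiles[p] for p in sorted(usable)},
        )
        spectra = compute_spectra(sub, n_points=config.dft_length)
        kernel = gk_matrix(spectra, alpha_prime=config.alpha_prime)
        alpha = kernel.alpha
        idx = np.array([network.index[p] for p in kernel.proteins])
        has_expr[idx] = True
        gk_full[np.ix_(idx, idx)] = kernel.matrix

    both_expr = np.outer(has_expr, has_expr)
    pa = np.where(both_expr, gk_full, tfp)

    w = np.zeros((n, n))
    edge = a == 1.0
    w[edge] = beta * pa[edge] + (1.0 - beta)
    bridge = (~edge) & (common >= 1.0) & both_expr
    w[bridge] = (tfp * gk_full)[bridge]
    np.fill_diagonal(w, 0.0)
    # exact symmetry: keep a single value per unordered pair
    w = np.triu(w, 1)
    w = w + w.T
    return WeightedPPIMatrix(matrix=w, bandwidth=alpha)
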