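"""Expression spectra, Gaussian kernel, topology similarity, weighted PPI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wpdinm import (
    ExpressionTable,
    PipelineConfig,
    ProteinNetwork,
    build_weighted_ppi,
    compute_spectra,
    dft_spectrum,
    gk_matrix,
    tfp_score,
)
from wpdinm.errors import DegenerateInputError, WpdinmError
from wpdinm.ppi_weighting import SpectrumTable


def naive_dft_magnitudes(series, n_points):
    """Independent oracle: literal double-loop sum over y = 1..M."""
    m = len(series)
    out = np.zeros(n_points)
    for t in range(n_points):
        acc = 0.0 + 0.0j
        for y in range(1, m + 1):
            acc += series[y - 1] * np.exp(-1j * 2 * np.pi * t * y / m)
        out[t] = abs(acc)
    return out


class TestDftSpectrum:
    def test_constant_signal_concentrates_at_dc(self):
        assert np.allclose(dft_spectrum([1, 1, 1, 1]), [4, 0, 0, 0], atol=1e-12)

    def test_impulse_has_flat_unit_spectrum(self):
        assert np.allclose(dft_spectrum([1, 0, 0, 0]), [1, 1, 1, 1], atol=1e-12)

    def test_parseval_on_ramp(self):
        spec = dft_spectrum([1, 2, 3, 4])
        assert np.sum(spec ** 2) == pytest.approx(120.0, rel=1e-12)

    def test_long_transform_repeats_with_period_m(self):
        # exponent base stays M, so components past M repeat the spectrum
        spec = dft_spectrum([1.0, 2.0, 3.0], n_points=7)
        assert np.allclose(spec[3:6], spec[:3], atol=1e-9)

    def test_n_shorter_than_series_rejected(self):
        with pytest.raises(WpdinmError):
            dft_spectrum([1, 2, 3], n_points=2)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=12),
           st.integers(0, 8))
    def test_matches_naive_oracle(self, series, extra):
        n = len(series) + extra
        got = dft_spectrum(series, n_points=n)
        assert np.allclose(got, naive_dft_magnitudes(series, n), atol=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=12))
    def test_parseval_identity(self, series):
        spec = dft_spectrum(series)
        m = len(series)
        lhs = float(np.sum(spec ** 2))
        rhs = m * float(np.sum(np.asarray(series) ** 2))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestGaussianKernel:
    def test_identical_spectra_give_unit_similarity(self):
        spectra = SpectrumTable(dft_length=2, magnitudes={
            "a": np.array([1.0, 2.0]), "b": np.array([1.0, 2.0])})
        k = gk_matrix(spectra)
        assert k.value("a", "b") == pytest.approx(1.0)

    def test_bandwidth_from_mean_squared_norm(self):
        spectra = SpectrumTable(dft_length=4,
                                magnitudes={"a": np.array([4.0, 0, 0, 0])})
        assert gk_matrix(spectra).alpha == pytest.approx(1 / 16)

    def test_orthogonal_unit_spectra(self):
        spectra = SpectrumTable(dft_length=2, magnitudes={
            "a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])})
        k = gk_matrix(spectra)
        assert k.alpha == pytest.approx(1.0)
        assert k.value("a", "b") == pytest.approx(np.exp(-2.0))

    def test_all_zero_spectra_degenerate(self):
        spectra = SpectrumTable(dft_length=2, magnitudes={
            "a": np.zeros(2), "b": np.zeros(2)})
        with pytest.raises(DegenerateInputError):
            gk_matrix(spectra)

    def test_order_invariance_and_monotonicity(self, rng):
        mags = {f"p{i}": rng.random(6) for i in range(5)}
        k1 = gk_matrix(SpectrumTable(6, dict(mags)))
        shuffled = dict(reversed(list(mags.items())))
        k2 = gk_matrix(SpectrumTable(6, shuffled))
        for a in mags:
            for b in mags:
                assert k1.value(a, b) == pytest.approx(k2.value(a, b))
        # similarity decreases with spectral distance
        base = np.zeros(6)
        near, far = base + 0.1, base + 2.0
        k = gk_matrix(SpectrumTable(6, {"o": base, "n": near, "f": far}))
        assert k.value("o", "n") > k.value("o", "f")


class TestTfpScore:
    def test_degree_two_pair_with_one_common_neighbor(self):
        # p1-p3, p1-p4, p2-p3, p2-p4: degrees 2 and 2, common {p3, p4}?
        # use: p1-c, p1-x, p2-c, p2-y -> one common neighbor c
        net = ProteinNetwork.from_edges(
            [("p1", "c"), ("p1", "x"), ("p2", "c"), ("p2", "y")])
        i, j = net.index["p1"], net.index["p2"]
        assert tfp_score(net, i, j) == pytest.approx(2 / 9)

    def test_two_isolated_proteins(self):
        net = ProteinNetwork.from_edges([("a", "b")], extra_ids=("x", "y"))
        assert tfp_score(net, net.index["x"], net.index["y"]) == 1.0

    def test_adjacent_degree_one_pair(self):
        net = ProteinNetwork.from_edges([("a", "b")])
        assert tfp_score(net, 0, 1) == pytest.approx(1 / 4)

    def test_self_pair_rejected(self):
        net = ProteinNetwork.from_edges([("a", "b")])
        with pytest.raises(WpdinmError):
            tfp_score(net, 0, 0)


class TestWeightedPpi:
    def _expr(self, net, values):
        m = len(next(iter(values.values())))
        return ExpressionTable(series_length=m,
                               profiles={k: np.array(v, float)
                                         for k, v in values.items()})

    def test_edge_mixes_kernel_with_offset(self):
        net = ProteinNetwork.from_edges([("a", "b")])
        expr = self._expr(net, {"a": [1.0, 2.0, 1.5], "b": [2.0, 1.0, 0.5]})
        cfg = PipelineConfig(beta=0.5)
        w = build_weighted_ppi(net, expr, cfg).matrix
        spectra = compute_spectra(expr)
        gk = gk_matrix(spectra).value("a", "b")
        assert w[0, 1] == pytest.approx(0.5 * gk + 0.5)
        assert (1 - 0.5) <= w[0, 1] <= 1.0

    def test_edge_without_expression_uses_topology(self):
        net = ProteinNetwork.from_edges([("a", "b"), ("b", "c")])
        expr = self._expr(net, {"a": [1.0, 2.0]})  # b, c unexpressed
        w = build_weighted_ppi(net, expr, PipelineConfig(beta=0.5)).matrix
        i, j = net.index["a"], net.index["b"]
        assert w[i, j] == pytest.approx(0.5 * tfp_score(net, i, j) + 0.5)

    def test_two_hop_pair_gets_product_weight(self):
        net = ProteinNetwork.from_edges([("a", "c"), ("c", "b")])
        expr = self._expr(net, {"a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0],
                                "c": [2.0, 2.0, 2.0]})
        w = build_weighted_ppi(net, expr, PipelineConfig()).matrix
        i, j = net.index["a"], net.index["b"]
        gk = gk_matrix(compute_spectra(self._expr(net, {
            "a": [1.0, 2.0, 3.0], "b": [3.0, 1.0, 2.0],
            "c": [2.0, 2.0, 2.0]}))).value("a", "b")
        assert w[i, j] == pytest.approx(tfp_score(net, i, j) * gk)

    def test_disconnected_pair_stays_zero(self):
        net = ProteinNetwork.from_edges([("a", "b"), ("c", "d")])
        expr = self._expr(net, {p: [1.0, float(k)] for k, p in
                                enumerate("abcd")})
        w = build_weighted_ppi(net, expr, PipelineConfig()).matrix
        assert w[net.index["a"], net.index["c"]] == 0.0

    def test_matrix_is_exactly_symmetric_with_zero_diagonal(self, seeded_bundle):
        w = build_weighted_ppi(seeded_bundle.network, seeded_bundle.expression,
                               seeded_bundle.config).matrix
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0.0)
        assert np.all(w >= 0.0)
        edge = seeded_bundle.network.adjacency == 1
        beta = seeded_bundle.config.beta
        assert np.all(w[edge] >= (1 - beta) - 1e-12)
        assert np.all(w[edge] <= 1.0 + 1e-12)
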