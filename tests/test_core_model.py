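"""Input parsing, network construction, ranking I/O and configuration."""

import numpy as np
import pytest

from wpdinm import PipelineConfig, ProteinNetwork, load_input_bundle
from wpdinm.errors import ConfigError, DimensionError, ParseError, WpdinmError
from wpdinm.io import (
    load_expression,
    load_network,
    read_ranking,
    write_edge_list,
    write_ranking,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestNetworkLoading:
    def test_duplicate_and_reversed_edges_collapse(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "p1\tp2\np2\tp1\np1\tp2\n")
        net = load_network(p)
        assert net.n_edges == 1
        assert net.edges == {frozenset(("p1", "p2"))}

    def test_self_loops_dropped(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "p1\tp1\np1\tp2\n")
        net = load_network(p)
        assert np.diag(net.adjacency).sum() == 0
        assert net.n_edges == 1

    def test_chain_adjacency(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "p1\tp2\np2\tp3\n")
        net = load_network(p)
        assert net.protein_ids == ["p1", "p2", "p3"]
        assert np.array_equal(net.adjacency, net.adjacency.T)
        assert np.triu(net.adjacency, 1).sum() == 2

    def test_first_appearance_order(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "z\ta\nb\tz\n")
        assert load_network(p).protein_ids == ["z", "a", "b"]

    def test_malformed_line_names_file_and_line(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "p1\tp2\np3\n")
        with pytest.raises(ParseError, match=r"ppi\.tsv:2"):
            load_network(p)

    def test_roundtrip_is_idempotent(self, tmp_path, rng):
        n = 30
        edges = []
        for _ in range(60):
            i, j = rng.integers(n, size=2)
            edges.append((f"p{i}", f"p{j}"))
        p1 = _write(tmp_path, "a.tsv", "".join(f"{a}\t{b}\n" for a, b in edges))
        net1 = load_network(p1)
        p2 = tmp_path / "b.tsv"
        write_edge_list(net1, p2)
        net2 = load_network(p2)
        assert net1.edges == net2.edges
        # edge count equals distinct unordered non-self pairs in the file
        distinct = {frozenset(e) for e in edges if e[0] != e[1]}
        assert net1.n_edges == len(distinct)


class TestExpressionLoading:
    def test_ragged_row_raises_dimension_error(self, tmp_path):
        p = _write(tmp_path, "expr.tsv", "p1\t1\t2\t3\np2\t1\t2\n")
        with pytest.raises(DimensionError):
            load_expression(p)

    def test_non_numeric_raises_parse_error(self, tmp_path):
        p = _write(tmp_path, "expr.tsv", "p1\t1\tx\t3\n")
        with pytest.raises(ParseError):
            load_expression(p)

    def test_profiles_loaded(self, tmp_path):
        p = _write(tmp_path, "expr.tsv", "p1\t1\t2\t3\n")
        table = load_expression(p)
        assert table.series_length == 3
        assert np.allclose(table.profiles["p1"], [1, 2, 3])


class TestBundleLoading:
    def test_unknown_protein_annotations_dropped(self, tmp_path):
        ppi = _write(tmp_path, "ppi.tsv", "p1\tp2\n")
        dom = _write(tmp_path, "dom.tsv", "p1\td1\npX\td2\n")
        bundle = load_input_bundle(ppi, domains_path=dom)
        assert bundle.domains.domain_ids == ["d1"]
        assert bundle.domains.matrix.shape == (2, 1)

    def test_missing_optional_files_yield_empty_structures(self, tmp_path):
        ppi = _write(tmp_path, "ppi.tsv", "p1\tp2\n")
        bundle = load_input_bundle(ppi)
        assert bundle.domains.n_domains == 0
        assert bundle.expression.coverage == set()
        assert bundle.subcellular.n_localizations == 0
        assert bundle.orthology.scores == {}

    def test_all_six_inputs(self, tmp_path):
        ppi = _write(tmp_path, "ppi.tsv", "p1\tp2\np2\tp3\n")
        dom = _write(tmp_path, "dom.tsv", "p1\td1\np2\td1\n")
        expr = _write(tmp_path, "expr.tsv", "p1\t1\t2\np2\t3\t4\n")
        sub = _write(tmp_path, "sub.tsv", "p1\tnucleus\n")
        orth = _write(tmp_path, "orth.tsv", "p1\t5\np3\t2\n")
        ess = _write(tmp_path, "ess.txt", "p1\n")
        bundle = load_input_bundle(ppi, dom, expr, sub, orth, ess)
        assert bundle.network.n_proteins == 3
        assert bundle.domains.matrix[:, 0].tolist() == [1, 1, 0]
        assert bundle.orthology.get("p3") == 2.0
        assert "p1" in bundle.essentials


class TestRankingIO:
    def test_descending_order(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_ranking([("b", 0.9), ("a", 0.5)], path)
        assert [pid for pid, _ in read_ranking(path)] == ["b", "a"]

    def test_tie_break_is_lexicographic(self, tmp_path):
        from wpdinm import rank_proteins
        ranked = rank_proteins(np.array([0.5, 0.5]), ["b", "a"])
        path = tmp_path / "r.tsv"
        write_ranking(ranked, path)
        assert [pid for pid, _ in read_ranking(path)] == ["a", "b"]

    def test_roundtrip_preserves_scores(self, tmp_path, rng):
        ranking = [(f"p{i}", float(s)) for i, s in
                   enumerate(sorted(rng.random(20), reverse=True))]
        path = tmp_path / "r.tsv"
        write_ranking(ranking, path)
        back = read_ranking(path)
        assert [p for p, _ in back] == [p for p, _ in ranking]
        assert np.allclose([s for _, s in back], [s for _, s in ranking],
                           atol=1e-12)

    def test_empty_ranking_rejected(self, tmp_path):
        with pytest.raises(WpdinmError):
            write_ranking([], tmp_path / "r.tsv")


class TestConfig:
    def test_defaults_match_reported_operating_point(self):
        cfg = PipelineConfig()
        assert (cfg.beta, cfg.omega, cfg.mu, cfg.rho) == (0.5, 0.7, 0.4, 0.85)
        assert (cfg.phi, cfg.theta, cfg.tau) == (0.25, 0.35, 0.45)
        assert cfg.epsilon == 1e-6

    @pytest.mark.parametrize(
        "field,value",
        [("beta", 1.5), ("rho", 0.0), ("mu", 1.0), ("epsilon", 0.0),
         ("phi", -0.1), ("alpha_prime", 0.0)],
    )
    def test_out_of_range_values_rejected(self, field, value):
        with pytest.raises(ConfigError):
            PipelineConfig(**{field: value})

    def test_renormalized_feature_weights_sum_to_one(self):
        cfg = PipelineConfig(renormalize_features=True)
        assert sum(cfg.feature_weights()) == pytest.approx(1.0)

    def test_from_yaml_file(self, tmp_path):
        p = _write(tmp_path, "c.yaml", "mu: 0.2\nrho: 0.9\n")
        cfg = PipelineConfig.from_file(p)
        assert cfg.mu == 0.2 and cfg.rho == 0.9

    def test_from_key_value_file(self, tmp_path):
        p = _write(tmp_path, "c.cfg", "mu=0.3\nbeta=0.6\n")
        cfg = PipelineConfig.from_file(p)
        assert cfg.mu == 0.3 and cfg.beta == 0.6

    def test_unknown_key_rejected(self, tmp_path):
        p = _write(tmp_path, "c.yaml", "not_a_knob: 1\n")
        with pytest.raises(ConfigError):
            PipelineConfig.from_file(p)
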