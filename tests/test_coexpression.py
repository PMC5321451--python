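"""Tests for Pearson kernels, network construction, and candidate ranking."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from lncsig.coexpression import (
    CoexpressionNetwork,
    _rowwise_correlation,
    build_network,
    correlation_pvalue,
    export_network,
    node_degree,
    pearson,
    read_network_tsv,
    select_candidates,
)
from lncsig.diffexp import differential_expression
from lncsig.errors import ConfigurationError, DataError


def pearson_oracle(x, y):
    """Textbook formula: covariance over the product of standard deviations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def t_two_sided_p_oracle(t, df):
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    tail, _ = quad(lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2), abs(t), np.inf)
    return 2.0 * tail


class TestPearson:
    def test_frozen_example(self):
        r = pearson([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert r == pytest.approx(0.9819805061, abs=1e-9)
        assert r == pytest.approx(pearson_oracle([1, 2, 3], [1, 2, 4]), abs=1e-12)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x, y = rng.normal(size=20), rng.normal(size=20)
            assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert pearson(x, y) == pytest.approx(pearson(y, x))
        assert pearson(2.0 * x + 5.0, y) == pytest.approx(pearson(x, y), abs=1e-12)
        assert pearson(-x, y) == pytest.approx(-pearson(x, y), abs=1e-12)

    def test_perfect_correlation(self):
        x = np.arange(5.0)
        assert pearson(x, 3 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(DataError):
            pearson([1.0, 2.0], [1.0, 2.0])  # too short
        with pytest.raises(DataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # constant


class TestCorrelationPvalue:
    @pytest.mark.parametrize("r,n", [(0.5, 10), (-0.8, 20), (0.95, 5), (0.0, 30)])
    def test_matches_t_transform_oracle(self, r, n):
        t = r * math.sqrt((n - 2) / (1 - r * r))
        assert correlation_pvalue(r, n) == pytest.approx(
            t_two_sided_p_oracle(t, n - 2), abs=1e-10
        )

    def test_limits_and_errors(self):
        assert correlation_pvalue(1.0, 5) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)
        with pytest.raises(DataError):
            correlation_pvalue(0.5, 2)
        with pytest.raises(DataError):
            correlation_pvalue(1.5, 10)

    def test_sign_symmetric(self):
        assert correlation_pvalue(0.6, 15) == pytest.approx(
            correlation_pvalue(-0.6, 15)
        )


class TestRowwiseCorrelation:
    def test_agrees_with_scalar_pearson(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=(4, 15)), rng.normal(size=(6, 15))
        r = _rowwise_correlation(a, b)
        assert r.shape == (4, 6)
        for i in range(4):
            for j in range(6):
                assert r[i, j] == pytest.approx(pearson(a[i], b[j]), abs=1e-12)


class TestBuildNetwork:
    def test_planted_block_edges(self, networks, expression_bundle, de_results):
        """Every reported edge passes both cutoffs, and the network degree
        identities hold: both sides' degree sums equal the edge count."""
        _, truth = expression_bundle
        network = networks["MM_vs_PM"]
        assert network.n_edges > 0
        assert (network.edges["r"].abs() > network.r_cutoff).all()
        assert (network.edges["p"] < network.p_cutoff).all()
        assert sum(network.degrees("lncrna").values()) == network.n_edges
        assert sum(network.degrees("mrna").values()) == network.n_edges
        signs = network.sign_counts()
        assert signs["positive"] + signs["negative"] == network.n_edges
        # the planted block driver dominates the reference-contrast network
        driver = truth.index[(truth["block"] == "block_down")
                             & (truth["block_role"] == "driver")][0]
        degrees = network.degrees("lncrna")
        assert degrees[driver] == max(degrees.values())

    def test_nodes_are_significant_probes(self, networks, de_results):
        for name, network in networks.items():
            lnc_sig = de_results[name]["lncRNA"].significant_probes
            mrna_sig = de_results[name]["mRNA"].significant_probes
            assert set(network.lncRNA_nodes) <= lnc_sig
            assert set(network.mRNA_nodes) <= mrna_sig

    def test_samples_default_to_contrast_union(self, networks, expression_bundle,
                                               design):
        matrix, _ = expression_bundle
        assert networks["PM_vs_N"].n_samples_used == design.n_primary + design.n_normal
        assert networks["MM_vs_PM"].n_samples_used == \
            design.n_metastatic + design.n_primary

    def test_empty_significant_sets(self, de_results, expression_bundle):
        matrix, _ = expression_bundle
        lnc = de_results["MM_vs_PM"]["lncRNA"]
        empty = type(lnc)(contrast=lnc.contrast, molecule_class="lncRNA",
                          table=lnc.table[lnc.table["direction"] == "never"])
        network = build_network(empty, de_results["MM_vs_PM"]["mRNA"], matrix)
        assert network.n_edges == 0

    def test_to_graph_attributes(self, networks):
        network = networks["MM_vs_PM"]
        graph = network.to_graph()
        assert graph.number_of_edges() == network.n_edges
        node = network.lncRNA_nodes[0]
        assert graph.nodes[node]["kind"] == "lncRNA"
        assert graph.nodes[node]["degree"] == node_degree(network, node)

    def test_node_degree_unknown_node(self, networks):
        with pytest.raises(DataError):
            node_degree(networks["MM_vs_PM"], "NOT_A_NODE")


class TestSelectCandidates:
    def _pool(self, de_results, expression_bundle):
        _, truth = expression_bundle
        return set(truth.index[(truth["molecule_class"] == "lncRNA")
                               & truth["pattern"].isin(["triple_up", "triple_down"])])

    def test_planted_driver_ranked_first(self, networks, de_results,
                                         expression_bundle):
        _, truth = expression_bundle
        pool = self._pool(de_results, expression_bundle)
        de_lnc = {name: r["lncRNA"] for name, r in de_results.items()}
        ranking = select_candidates(networks, de_lnc, pool,
                                    reference_contrast="MM_vs_PM", k=5)
        driver = truth.index[(truth["block"] == "block_down")
                             & (truth["block_role"] == "driver")][0]
        assert ranking.table.index[0] == driver
        assert list(ranking.table["rank"]) == [1, 2, 3, 4, 5]
        assert ranking.table["degree"].is_monotonic_decreasing

    def test_tie_breaks(self, networks, de_results, expression_bundle):
        pool = self._pool(de_results, expression_bundle)
        de_lnc = {name: r["lncRNA"] for name, r in de_results.items()}
        full = select_candidates(networks, de_lnc, pool,
                                 reference_contrast="MM_vs_PM", k=len(pool)).table
        for (_, a), (_, b) in zip(full.iterrows(), full.iloc[1:].iterrows()):
            key_a = (-a["degree"], -a["abs_log2fc"], a["p_adj"], a.name)
            key_b = (-b["degree"], -b["abs_log2fc"], b["p_adj"], b.name)
            assert key_a <= key_b

    def test_unknown_reference_contrast(self, networks, de_results):
        de_lnc = {name: r["lncRNA"] for name, r in de_results.items()}
        with pytest.raises(ConfigurationError):
            select_candidates(networks, de_lnc, set(), reference_contrast="X")

    def test_candidate_missing_from_de_table(self, networks, de_results):
        de_lnc = {name: r["lncRNA"] for name, r in de_results.items()}
        with pytest.raises(DataError):
            select_candidates(networks, de_lnc, {"NOT_A_PROBE"},
                              reference_contrast="MM_vs_PM")


class TestExport:
    def test_tsv_round_trip(self, networks):
        network = networks["MM_vs_PM"]
        buffer = io.StringIO()
        export_network(network, "tsv", buffer)
        buffer.seek(0)
        again = read_network_tsv(buffer)
        assert again.n_edges == network.n_edges
        assert again.lncRNA_nodes == network.lncRNA_nodes
        np.testing.assert_allclose(again.edges["r"], network.edges["r"], rtol=1e-9)
        assert list(again.edges["sign"]) == list(network.edges["sign"])

    def test_sif_format(self, networks):
        network = networks["MM_vs_PM"]
        buffer = io.StringIO()
        export_network(network, "sif", buffer)
        lines = buffer.getvalue().splitlines()
        assert len(lines) == network.n_edges
        for line in lines:
            source, label, target = line.split(" ")
            assert label in ("pos", "neg")

    def test_graphml_parses(self, networks):
        import networkx as nx

        buffer = io.StringIO()
        export_network(networks["MM_vs_PM"], "graphml", buffer)
        graph = nx.read_graphml(io.BytesIO(buffer.getvalue().encode()))
        assert graph.number_of_edges() == networks["MM_vs_PM"].n_edges

    def test_unknown_format(self, networks):
        with pytest.raises(ConfigurationError):
            export_network(networks["MM_vs_PM"], "gexf", io.StringIO())

    def test_read_rejects_missing_columns(self):
        with pytest.raises(DataError):
            read_network_tsv(io.StringIO("lncrna\tmrna\n"))
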