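import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microtempo.datamodel import AssociationNetwork, CountTable, SampleTable
from microtempo import networks as nw


def _net(edges, attrs=None):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, sign=1, weight=0.5, cooccurrence_score=1.0)
    if attrs:
        for n, a in attrs.items():
            if n not in g:
                g.add_node(n)
            g.nodes[n].update(a)
    return AssociationNetwork(g)


class TestCLR:
    def test_equal_counts_all_zero(self):
        t = CountTable(pd.DataFrame([[7, 7, 7]], index=["s"], columns=list("abc")))
        assert np.allclose(nw.clr_transform(t).counts, 0.0)

    def test_rows_centred(self, tiny_scenario):
        clr = nw.clr_transform(tiny_scenario.table)
        assert np.abs(clr.counts.sum(axis=1)).max() < 1e-9

    def test_two_taxon_closed_form(self):
        t = CountTable(pd.DataFrame([[10, 1]], index=["s"], columns=["a", "b"]))
        y = nw.clr_transform(t).counts[0]
        expect = 0.5 * np.log(11 / 2)
        assert y[0] == pytest.approx(expect, abs=1e-4)
        assert y[1] == pytest.approx(-expect, abs=1e-4)


class TestCooccurrenceFilter:
    def _detection(self):
        # A&B together in all 5 samples; A&C only in 2 of 5
        return pd.DataFrame(
            {
                "A": [1, 1, 1, 1, 1],
                "B": [2, 1, 3, 1, 1],
                "C": [1, 1, 0, 0, 0],
            },
            index=[f"s{i}" for i in range(5)],
        )

    def test_keep_drop_and_isolates(self):
        net = _net([("A", "B"), ("A", "C")])
        out = nw.cooccurrence_filter(net, self._detection(), min_score=0.5)
        assert ("A", "B") in out.graph.edges or ("B", "A") in out.graph.edges
        assert not out.graph.has_edge("A", "C")
        assert "C" not in out.graph  # isolated after the filter

    def test_missing_node_errors(self):
        net = _net([("A", "Z")])
        with pytest.raises(Exception, match="missing"):
            nw.cooccurrence_filter(net, self._detection())


class TestMonthlySubnetworks:
    def _inputs(self):
        counts = pd.DataFrame(
            [[1, 1, 1], [1, 0, 1], [0, 0, 1]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C"],
        )
        table = CountTable(counts)
        meta = SampleTable(
            pd.DataFrame(
                {
                    "date": ["2013-04-15", "2013-05-15", "2013-06-15"],
                    "site": "X",
                    "size_fraction": "small",
                },
                index=["s1", "s2", "s3"],
            )
        )
        net = _net([("A", "B"), ("B", "C"), ("A", "C")])
        return net, table, meta

    def test_all_detected_month_reproduces_static(self):
        net, table, meta = self._inputs()
        series = nw.monthly_subnetworks(net, table, meta)
        m = series.subnetworks["2013-04"]
        assert set(m.graph.nodes()) == set(net.graph.nodes())
        assert set(map(frozenset, m.graph.edges())) == set(
            map(frozenset, net.graph.edges())
        )

    def test_undetected_node_loses_all_edges(self):
        net, table, meta = self._inputs()
        series = nw.monthly_subnetworks(net, table, meta)
        m = series.subnetworks["2013-05"]  # B undetected
        assert "B" not in m.graph
        assert set(map(frozenset, m.graph.edges())) == {frozenset(("A", "C"))}

    def test_subset_property_and_monotonicity(self):
        net, table, meta = self._inputs()
        series = nw.monthly_subnetworks(net, table, meta)
        months = sorted(series.subnetworks)
        static_edges = set(map(frozenset, net.graph.edges()))
        node_sets = {m: set(series.subnetworks[m].graph.nodes()) for m in months}
        edge_sets = {
            m: set(map(frozenset, series.subnetworks[m].graph.edges()))
            for m in months
        }
        for m in months:
            assert edge_sets[m] <= static_edges
        for m1 in months:
            for m2 in months:
                if node_sets[m1] >= node_sets[m2]:
                    assert edge_sets[m1] >= edge_sets[m2]


class TestMetrics:
    def test_triangle(self):
        m = nw.network_metrics(_net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert m["edge_density"] == pytest.approx(1.0)
        assert m["transitivity"] == pytest.approx(1.0)
        assert m["average_path_length"] == pytest.approx(1.0)

    def test_path(self):
        m = nw.network_metrics(_net([("a", "b"), ("b", "c")]))
        assert m["edge_density"] == pytest.approx(2 / 3)
        assert m["transitivity"] == pytest.approx(0.0)
        assert m["average_path_length"] == pytest.approx(4 / 3)

    def test_star_degree_assortativity(self):
        m = nw.network_metrics(
            _net([("hub", x) for x in ["l1", "l2", "l3", "l4"]])
        )
        assert m["assortativity_degree"] == pytest.approx(-1.0)

    def test_two_pure_cliques_domain_assortativity(self):
        prok = [("p1", "p2"), ("p2", "p3"), ("p1", "p3")]
        euk = [("e1", "e2"), ("e2", "e3"), ("e1", "e3")]
        attrs = {f"p{i}": {"domain_marker": "16S"} for i in range(1, 4)}
        attrs.update({f"e{i}": {"domain_marker": "18S"} for i in range(1, 4)})
        m = nw.network_metrics(_net(prok + euk, attrs))
        assert m["assortativity_domain"] == pytest.approx(1.0)

    def test_undefined_metrics_reported_missing(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        m = nw.network_metrics(AssociationNetwork(g))
        assert np.isnan(m["average_path_length"])
        assert np.isnan(m["mean_positive_strength"])

    def test_mean_positive_strength_over_edges(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign=1, weight=0.8)
        g.add_edge("b", "c", sign=1, weight=0.4)
        g.add_edge("a", "c", sign=-1, weight=-0.9)
        m = nw.network_metrics(AssociationNetwork(g))
        assert m["mean_positive_strength"] == pytest.approx(0.6)


def holm_step_down(pvals):
    """Independent closed-form Holm step-down for the cross-check."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestCorrelations:
    def _series_env(self):
        idx = [f"2013-{m:02d}" for m in range(1, 11)]
        metrics = pd.DataFrame(
            {"edge_density": np.linspace(0.1, 0.9, 10)}, index=idx
        )
        env = pd.DataFrame({"temperature": np.linspace(5, 25, 10)}, index=idx)
        return metrics, env

    def test_monotone_gives_rho_one(self):
        metrics, env = self._series_env()
        out = nw.metric_env_correlations(metrics, env)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_holm_worked_example(self):
        adj = holm_step_down([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_holm_matches_independent_step_down(self):
        rng = np.random.default_rng(14)
        from statsmodels.stats.multitest import multipletests

        for n in range(1, 21):
            p = rng.uniform(size=n)
            assert np.allclose(
                multipletests(p, method="holm")[1], holm_step_down(p)
            )

    def test_adjusted_at_least_raw(self, tiny_scenario):
        rng = np.random.default_rng(2)
        idx = [f"m{i}" for i in range(12)]
        metrics = pd.DataFrame(rng.normal(size=(12, 3)), index=idx, columns=list("abc"))
        env = pd.DataFrame(rng.normal(size=(12, 2)), index=idx, columns=["t", "d"])
        out = nw.metric_env_correlations(metrics, env)
        ok = out["p"].notna()
        assert (out.loc[ok, "p_holm"] >= out.loc[ok, "p"] - 1e-12).all()

    def test_too_few_pairs_flagged(self):
        metrics = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan, np.nan]},
                               index=list("abcde"))
        env = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        out = nw.metric_env_correlations(metrics, env)
        assert np.isnan(out.loc[0, "rho"])
        assert "fewer than" in out.loc[0, "note"]
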