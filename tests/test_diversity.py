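import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, spearmanr

from microtempo.datamodel import CountTable, SampleTable, ValidationError
from microtempo import diversity as dv


class TestRarefy:
    def test_depth_equal_total_unchanged(self, small_table):
        out = dv.rarefy(small_table, 6, seed=0, drop_shallow=True)
        pd.testing.assert_series_equal(
            out.data.loc["s3"], small_table.data.loc["s3"], check_dtype=False
        )

    def test_totals_conserved(self, small_table):
        out = dv.rarefy(small_table, 5, seed=0)
        assert (out.totals() == 5).all()

    def test_shallow_sample_raises_without_flag(self, small_table):
        with pytest.raises(ValidationError, match="below rarefaction depth"):
            dv.rarefy(small_table, 8, seed=0)

    def test_expected_richness_matches_hypergeometric(self):
        # E[S] = sum_i [1 - C(T - n_i, d)/C(T, d)], via hypergeom survival
        counts = np.array([12, 7, 3, 1, 0])
        T, d = counts.sum(), 10
        expected = sum(1 - hypergeom.pmf(0, T, n, d) for n in counts if n > 0)
        table = CountTable(
            pd.DataFrame([counts], index=["s"], columns=list("abcde"))
        )
        rich = [
            (dv.rarefy(table, d, seed=s).counts > 0).sum() for s in range(1000)
        ]
        assert np.mean(rich) == pytest.approx(expected, abs=0.05)

    def test_measure_preserving_in_expectation(self):
        counts = np.array([40, 25, 10, 5])
        table = CountTable(pd.DataFrame([counts], index=["s"], columns=list("abcd")))
        f = counts / counts.sum()
        mean_f = np.mean(
            [dv.rarefy(table, 20, seed=s).relative().to_numpy()[0] for s in range(1000)],
            axis=0,
        )
        assert np.allclose(mean_f, f, atol=0.02)


class TestAlpha:
    def test_uniform_four_taxa(self):
        t = CountTable(pd.DataFrame([[5, 5, 5, 5]], index=["s"], columns=list("abcd")))
        a = dv.alpha_diversity(t)
        assert a.loc["s", "shannon"] == pytest.approx(np.log(4))
        assert a.loc["s", "pielou"] == pytest.approx(1.0)

    def test_single_taxon(self):
        t = CountTable(pd.DataFrame([[9, 0]], index=["s"], columns=["a", "b"]))
        a = dv.alpha_diversity(t)
        assert a.loc["s", "shannon"] == 0.0
        assert np.isnan(a.loc["s", "pielou"])

    def test_faith_pd_all_tips(self, three_tip_tree):
        t = CountTable(
            pd.DataFrame([[1, 1, 1], [1, 1, 0]], index=["s1", "s2"], columns=list("ABC"))
        )
        a = dv.alpha_diversity(t, tree=three_tip_tree)
        assert a.loc["s1", "faith_pd"] == pytest.approx(
            three_tip_tree.total_branch_length()
        )
        # A and B span A:1 + B:1 + internal:1
        assert a.loc["s2", "faith_pd"] == pytest.approx(3.0)


class TestRankAbundance:
    def test_example_and_normalisation(self):
        t = CountTable(pd.DataFrame([[6, 3, 1]], index=["s"], columns=list("abc")))
        ra = dv.rank_abundance(t)
        assert list(ra["rel_abundance"]) == pytest.approx([0.6, 0.3, 0.1])
        assert list(ra["rank"]) == [1, 2, 3]
        assert ra["rel_abundance"].sum() == pytest.approx(1.0)

    def test_ties_broken_by_asv_id(self):
        t = CountTable(pd.DataFrame([[3, 3, 3]], index=["s"], columns=["z", "a", "m"]))
        ra = dv.rank_abundance(t)
        assert list(ra["asv_id"]) == ["a", "m", "z"]


class TestBrayCurtis:
    def test_limits_and_hand_value(self):
        t = CountTable(
            pd.DataFrame(
                [[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]],
                index=list("jklm"),
                columns=list("abc"),
            )
        )
        d = dv.bray_curtis(t)
        assert d.to_frame().loc["j", "l"] == pytest.approx(0.0)
        assert d.to_frame().loc["k", "m"] == pytest.approx(1.0)
        assert d.to_frame().loc["j", "k"] == pytest.approx(0.5)

    def test_semimetric_properties(self, tiny_scenario):
        d = dv.bray_curtis(tiny_scenario.table).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


def _split_fixture():
    ids = [f"x{i}" for i in range(3)] + [f"y{i}" for i in range(3)]
    d = np.ones((6, 6))
    d[:3, :3] = 0
    d[3:, 3:] = 0
    np.fill_diagonal(d, 0)
    dist = dv.DistanceMatrix(ids=ids, data=d)
    meta = pd.DataFrame({"grp": ["A"] * 3 + ["B"] * 3}, index=ids)
    return dist, meta


class TestPermanova:
    def test_perfect_separation_r2_one_exhaustive_p(self):
        dist, meta = _split_fixture()
        res = dv.permanova(dist, meta, ["grp"], permutations="exhaustive")
        assert res.r2("grp") == pytest.approx(1.0)
        assert res.p("grp") == pytest.approx(0.1)

    def test_r2_sums_to_one(self, tiny_scenario):
        bc = dv.bray_curtis(tiny_scenario.table)
        res = dv.permanova(
            bc, tiny_scenario.meta, ["site"], n_perm=49, seed=0
        )
        assert res.table["R2"].sum() == pytest.approx(1.0)
        assert ((res.table["R2"] >= 0) & (res.table["R2"] <= 1)).all()

    def test_pseudo_f_matches_skbio(self, tiny_scenario):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        bc = dv.bray_curtis(tiny_scenario.table)
        ours = dv.permanova(bc, tiny_scenario.meta, ["site"], n_perm=19, seed=0)
        theirs = sk_permanova(
            SkDM(bc.data, ids=bc.ids),
            tiny_scenario.meta.data,
            column="site",
            permutations=9,
        )
        ours_f = float(ours.table.set_index("term").loc["site", "F"])
        assert ours_f == pytest.approx(float(theirs["test statistic"]), rel=1e-8)

    def test_null_p_uniform(self):
        # labels independent of distances -> p ~ U(0,1)
        from scipy.stats import kstest

        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=(12, 4))
            d = dv.DistanceMatrix(
                ids=[f"s{i}" for i in range(12)],
                data=np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1)),
            )
            meta = pd.DataFrame(
                {"grp": rng.permutation(["A"] * 6 + ["B"] * 6)},
                index=d.ids,
            )
            pvals.append(
                dv.permanova(d, meta, ["grp"], n_perm=99, seed=int(rng.integers(2**31))).p("grp")
            )
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_level_term_rejected(self):
        dist, meta = _split_fixture()
        meta["one"] = "same"
        with pytest.raises(ValidationError, match="single level"):
            dv.permanova(dist, meta, ["one"], n_perm=9, seed=0)


class TestTimeDecay:
    def _dist_meta(self, n=6):
        rng = np.random.default_rng(0)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) / n
        ids = [f"s{i}" for i in range(n)]
        dates = pd.date_range("2013-04-15", periods=n, freq="MS")
        meta = SampleTable(
            pd.DataFrame(
                {"date": dates.strftime("%Y-%m-%d"), "site": "X", "size_fraction": "s"},
                index=ids,
            )
        )
        return dv.DistanceMatrix(ids=ids, data=d), meta

    def test_pair_count_and_positivity(self):
        dist, meta = self._dist_meta()
        td = dv.time_decay(dist, meta)
        assert len(td) == 6 * 5 // 2
        assert (td["delta_months"] > 0).all()

    def test_monotone_drift_series_has_positive_decay(self):
        dist, meta = self._dist_meta(10)
        td = dv.time_decay(dist, meta)
        rho, _ = spearmanr(td["delta_months"], td["dissimilarity"])
        assert rho > 0
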