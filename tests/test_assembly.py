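import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microtempo.datamodel import CountTable, PhyloTree
from microtempo import assembly as asm
from microtempo.synthetic import simulate_tree


def brute_force_beta_mntd(counts: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Independent double-loop evaluation of the abundance-weighted
    beta mean nearest taxon distance."""
    S, T = counts.shape
    f = counts / counts.sum(axis=1, keepdims=True)
    out = np.zeros((S, S))
    for j in range(S):
        for k in range(S):
            if j == k:
                continue
            in_j = [i for i in range(T) if counts[j, i] > 0]
            in_k = [i for i in range(T) if counts[k, i] > 0]
            a = sum(f[j, i] * min(D[i, ip] for ip in in_k) for i in in_j)
            b = sum(f[k, ip] * min(D[ip, i] for i in in_j) for ip in in_k)
            out[j, k] = 0.5 * (a + b)
    return out


def _random_instance(rng, n_taxa, n_samples):
    tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
    D = tree.cophenetic()
    while True:
        counts = rng.integers(0, 6, size=(n_samples, n_taxa))
        if (counts.sum(axis=1) > 0).all():
            break
    table = CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=list(D.index),
        )
    )
    return table, D


class TestCophenetic:
    def test_path_sums(self, three_tip_tree):
        d = asm.cophenetic_distances(three_tip_tree)
        assert d.loc["A", "B"] == pytest.approx(3.0)
        assert d.loc["B", "C"] == pytest.approx(2.0)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)


class TestBetaMNTD:
    def test_identical_communities_are_zero(self, three_tip_tree):
        t = CountTable(
            pd.DataFrame([[2, 1, 1], [2, 1, 1]], index=["s1", "s2"], columns=list("ABC"))
        )
        b = asm.beta_mntd(t, three_tip_tree.cophenetic())
        assert b.loc["s1", "s2"] == pytest.approx(0.0)

    def test_hand_worked_example(self):
        # j = {A:1}, k = {B:.5, C:.5}; d(A,B)=2, d(A,C)=6, d(B,C)=6
        tree = PhyloTree(TreeNode.read(["((A:1,B:1):2,C:3);"]))
        d = tree.cophenetic()
        assert d.loc["A", "B"] == 2 and d.loc["A", "C"] == 6 and d.loc["B", "C"] == 6
        t = CountTable(
            pd.DataFrame([[4, 0, 0], [0, 3, 3]], index=["j", "k"], columns=list("ABC"))
        )
        b = asm.beta_mntd(t, d)
        assert b.loc["j", "k"] == pytest.approx(3.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_taxa = int(rng.integers(3, 9))
            n_samples = int(rng.integers(2, 7))
            table, D = _random_instance(rng, n_taxa, n_samples)
            fast = asm.beta_mntd(table, D).to_numpy()
            slow = brute_force_beta_mntd(
                table.counts.astype(float), D.to_numpy()
            )
            assert np.abs(fast - slow).max() < 1e-10


class TestBNTI:
    def test_star_tree_degenerate(self):
        # all tip pairs equidistant: shuffles change nothing
        tree = PhyloTree(TreeNode.read(["(A:1,B:1,C:1,D:1);"]))
        t = CountTable(
            pd.DataFrame(
                [[3, 1, 0, 0], [0, 0, 2, 2], [1, 1, 1, 1]],
                index=["s1", "s2", "s3"],
                columns=list("ABCD"),
            )
        )
        z, flags, _ = asm.bnti(t, tree, n_null=49, seed=0)
        iu = np.triu_indices(3, 1)
        assert flags.to_numpy()[iu].all()
        assert np.allclose(z.to_numpy()[iu], 0.0)

    def test_identical_communities_degenerate(self, three_tip_tree):
        t = CountTable(
            pd.DataFrame([[2, 1, 1], [2, 1, 1]], index=["s1", "s2"], columns=list("ABC"))
        )
        z, flags, _ = asm.bnti(t, three_tip_tree, n_null=49, seed=0)
        assert flags.loc["s1", "s2"]
        assert z.loc["s1", "s2"] == 0.0

    def test_invariant_to_branch_length_rescaling(self):
        rng = np.random.default_rng(23)
        table, D = _random_instance(rng, 8, 5)
        z1, _, _ = asm.bnti(table, D, n_null=99, seed=7)
        z2, _, _ = asm.bnti(table, 10.0 * D, n_null=99, seed=7)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_null_calibration_without_phylogenetic_signal(self):
        # tip labels shuffled -> no signal -> few |z| > 2
        rng = np.random.default_rng(31)
        tree = simulate_tree(50, seed=int(rng.integers(2**31)))
        D = tree.cophenetic()
        perm = rng.permutation(list(D.index))
        D_shuffled = pd.DataFrame(D.to_numpy(), index=perm, columns=perm)
        counts = rng.integers(0, 30, size=(12, 50))
        table = CountTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(12)], columns=perm)
        )
        z, _, _ = asm.bnti(table, D_shuffled, n_null=199, seed=3)
        frac = (np.abs(z.to_numpy()[np.triu_indices(12, 1)]) > 2).mean()
        assert frac < 0.15

    def test_n_null_too_small(self, three_tip_tree, small_table):
        t = CountTable(small_table.data.rename(columns=dict(zip("abc", "ABC"))))
        with pytest.raises(Exception, match="n_null"):
            asm.bnti(t, three_tip_tree, n_null=1, seed=0)


class TestRaupCrick:
    def test_upper_bound_attained(self):
        # two-taxon dataset: nulls always share both taxa, so the
        # near-disjoint observed pair beats every null
        t = CountTable(
            pd.DataFrame(
                [[100, 1], [1, 100], [50, 50], [60, 40]],
                index=["s1", "s2", "s3", "s4"],
                columns=["a", "b"],
            )
        )
        rc = asm.raup_crick_bray(t, n_null=199, seed=1)
        assert rc.loc["s1", "s2"] == pytest.approx(1.0)

    def test_lower_bound_for_identical_pair(self):
        rng = np.random.default_rng(2)
        base = rng.integers(20, 120, size=10)
        t = CountTable(
            pd.DataFrame(
                [base, base, rng.integers(20, 120, size=10)],
                index=["s1", "s2", "s3"],
                columns=[f"t{i}" for i in range(10)],
            )
        )
        rc = asm.raup_crick_bray(t, n_null=199, seed=3)
        assert rc.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_bounds_always_hold(self, tiny_scenario):
        sub = tiny_scenario.site_table("temperate")
        sub = sub.select_samples(sub.sample_ids[:8])
        rc = asm.raup_crick_bray(sub, n_null=49, seed=0).to_numpy()
        assert rc.min() >= -1.0 and rc.max() <= 1.0

    def test_non_integer_counts_rejected(self):
        from microtempo.networks import clr_transform

        t = CountTable(pd.DataFrame([[3, 1], [1, 3]], index=["a", "b"], columns=["x", "y"]))
        with pytest.raises(Exception, match="integer"):
            asm.raup_crick_bray(clr_transform(t), n_null=19, seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "b, r, expected",
        [
            (2.5, 0.0, "heterogeneous selection"),
            (-2.5, 0.0, "homogeneous selection"),
            (0.0, 0.97, "historical contingency"),
            (0.0, -0.97, "non-selective low turnover"),
            (0.0, 0.0, "ecological drift"),
            (2.0, 0.99, "historical contingency"),  # boundary: |bNTI| <= 2
            (1.9, -0.95, "ecological drift"),       # boundary: |RC| <= 0.95
        ],
    )
    def test_threshold_table(self, b, r, expected):
        ids = ["s1", "s2"]
        bm = pd.DataFrame([[0, b], [b, 0]], index=ids, columns=ids)
        rm = pd.DataFrame([[0, r], [r, 0]], index=ids, columns=ids)
        out = asm.classify_processes(bm, rm)
        assert out.loc[0, "process"] == expected

    def test_degenerate_pairs_use_rc_branch(self):
        ids = ["s1", "s2"]
        bm = pd.DataFrame(0.0, index=ids, columns=ids)
        rm = pd.DataFrame([[0, 0.99], [0.99, 0]], index=ids, columns=ids)
        flags = pd.DataFrame(True, index=ids, columns=ids)
        out = asm.classify_processes(bm, rm, degenerate=flags)
        assert out.loc[0, "process"] == "historical contingency"
        assert out.loc[0, "degenerate"]


class TestFractions:
    def test_counting(self):
        labels = pd.DataFrame(
            {
                "sample_j": ["a"] * 10,
                "sample_k": [f"b{i}" for i in range(10)],
                "process": ["heterogeneous selection"] * 4 + ["ecological drift"] * 6,
            }
        )
        f = asm.process_fractions(labels)
        assert f.loc[0, "heterogeneous selection"] == pytest.approx(0.4)
        assert f.loc[0, "ecological drift"] == pytest.approx(0.6)
        assert sum(f.loc[0, p] for p in asm.PROCESSES) == pytest.approx(1.0)
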