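"""PIC, Blomberg's K (dual path), tip-shuffle randomization, selection."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from phyllomatch import (
    FunctionTable,
    blomberg_k,
    one_sample_per_species,
    pic,
    select_signal_functions,
    signal_all,
    signal_test,
    simulate_bm_trait,
    simulate_tree,
)
from phyllomatch.phylosignal import (
    SignalResult,
    phylo_covariance,
    signal_table,
    tree_to_arrays,
)


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestPIC:
    def test_two_tip_formula(self):
        t = newick("(a:1,b:3);")
        c = pic(t, pd.Series({"a": 3.0, "b": 1.0}))
        assert abs(c.iloc[0]) == pytest.approx((3 - 1) / np.sqrt(4), abs=1e-14)

    def test_constant_trait_zero_contrasts(self):
        t = newick("((a:1,b:1):1,(c:1,d:1):1);")
        c = pic(t, pd.Series({k: 2.5 for k in "abcd"}))
        assert np.allclose(c, 0.0)

    def test_matches_ape_on_fixed_four_tip_tree(self):
        # frozen reference contrasts from ape::pic on the same tree and trait
        t = newick("((a:1.0,b:2.0):0.5,(c:1.5,d:0.5):1.0);")
        c = pic(t, pd.Series({"a": 1.0, "b": 4.0, "c": 2.0, "d": 8.0}))
        expected = sorted([2.82262521684231, 1.73205080756888, 4.24264068711928])
        assert sorted(np.abs(c)) == pytest.approx(expected, abs=1e-12)

    def test_matches_gls_quadratic_form(self):
        # contrast sum of squares equals the GLS residual quadratic form
        tree = simulate_tree(6, 1.0, seed=3)
        arrays = tree_to_arrays(tree)
        x = simulate_bm_trait(tree, 1.0, seed=4)
        vec = np.array([x[t] for t in arrays.tip_labels])
        c = pic(arrays, vec)
        V = phylo_covariance(arrays)
        Vinv = np.linalg.inv(V)
        ones = np.ones(len(vec))
        a = (ones @ Vinv @ vec) / (ones @ Vinv @ ones)
        assert (c**2).sum() == pytest.approx((vec - a) @ Vinv @ (vec - a), abs=1e-10)

    def test_id_mismatch_reports_symmetric_difference(self):
        t = newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="mismatch"):
            pic(t, pd.Series({"a": 1.0, "z": 2.0}))

    def test_polytomy_resolved_matches_star_covariance(self):
        star = newick("(a:2,b:2,c:2,d:2);")
        V = phylo_covariance(tree_to_arrays(star))
        np.testing.assert_allclose(V, np.diag([2.0] * 4), atol=1e-12)


class TestBlombergK:
    def test_star_tree_equal_branches_k_is_one(self):
        star = newick("(a:1.5,b:1.5,c:1.5,d:1.5,e:1.5);")
        for vals in ([1.0, 3.0, -2.0, 0.5, 7.0], [0.0, 1.0, 0.0, 0.0, 2.0]):
            x = pd.Series(dict(zip("abcde", vals)))
            assert blomberg_k(star, x).K == pytest.approx(1.0, abs=1e-10)

    def test_matches_frozen_picante_value(self):
        # picante::Kcalc on this exact tree/trait gives 1.2484241038439
        tree = simulate_tree(8, 1.0, seed=42)
        x = simulate_bm_trait(tree, 1.0, seed=7)
        assert blomberg_k(tree, x).K == pytest.approx(1.2484241038439, abs=1e-10)

    def test_dual_path_equivalence(self):
        rng = np.random.default_rng(0)
        for i in range(20):
            tree = simulate_tree(8, 1.0, seed=100 + i)
            x = pd.Series(rng.normal(size=8), index=[f"host{j+1}" for j in range(8)])
            fast = blomberg_k(tree, x, method="pic")
            slow = blomberg_k(tree, x, method="vcv")
            assert fast.K == pytest.approx(slow.K, abs=1e-8)
            assert fast.mse_ratio_obs == pytest.approx(slow.mse_ratio_obs, abs=1e-8)

    def test_k_invariances(self):
        tree = simulate_tree(10, 1.0, seed=5)
        x = simulate_bm_trait(tree, 1.0, seed=6)
        k0 = blomberg_k(tree, x).K
        assert blomberg_k(tree, 3.0 * x - 7.0).K == pytest.approx(k0, abs=1e-9)
        scaled = tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 13.7
        assert blomberg_k(scaled, x).K == pytest.approx(k0, abs=1e-9)

    def test_clade_indicator_conservatism_k_above_one(self):
        # deep split, one clade shifted far: stronger-than-Brownian signal
        t = newick("(((a:1,b:1):1,(c:1,d:1):1):3,((e:1,f:1):1,(g:1,h:1):1):3);")
        x = pd.Series({k: (100.0 if k in "abcd" else 0.0) for k in "abcdefgh"})
        x += pd.Series({k: i * 0.01 for i, k in enumerate("abcdefgh")})  # break ties
        res = blomberg_k(t, x)
        assert res.K > 1.0
        assert res.K == pytest.approx(blomberg_k(t, x, method="vcv").K, abs=1e-8)

    def test_constant_trait_rejected(self):
        t = newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(t, pd.Series({"a": 1.0, "b": 1.0}))

    def test_k_consistency_identity(self):
        tree = simulate_tree(12, 1.0, seed=9)
        x = simulate_bm_trait(tree, 2.0, seed=10)
        r = blomberg_k(tree, x)
        assert r.K == pytest.approx(r.mse_ratio_obs / r.mse_ratio_exp, abs=1e-10)


class TestSignalTest:
    def test_p_value_lower_bound(self):
        tree = simulate_tree(8, 1.0, seed=1)
        x = simulate_bm_trait(tree, 1.0, seed=2)
        r = signal_test(tree, x, n_rand=999, seed=0)
        assert r.p_value >= 1 / 1000
        assert r.n_randomizations == 999

    def test_deterministic_given_seed(self):
        tree = simulate_tree(10, 1.0, seed=2)
        x = simulate_bm_trait(tree, 1.0, seed=3)
        assert (
            signal_test(tree, x, n_rand=199, seed=4).p_value
            == signal_test(tree, x, n_rand=199, seed=4).p_value
        )

    def test_type_one_error_quick(self):
        # shuffled (exchangeable) traits: rejection rate near alpha
        tree = simulate_tree(16, 1.0, seed=11)
        arrays = tree_to_arrays(tree)
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for i in range(reps):
            x = pd.Series(rng.normal(size=16), index=arrays.tip_labels)
            if signal_test(arrays, x, n_rand=199, seed=i).p_value < 0.05:
                hits += 1
        assert 0.01 < hits / reps < 0.10

    def test_bm_power_on_32_tips(self):
        # strong Brownian signal should usually be detected
        hits = 0
        reps = 60
        for i in range(reps):
            tree = simulate_tree(32, 1.0, seed=500 + i)
            x = simulate_bm_trait(tree, 5.0, seed=900 + i)
            if signal_test(tree, x, n_rand=199, seed=i).p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.70


class TestSubsampleAndSelection:
    def _two_sample_table(self):
        df = pd.DataFrame(
            np.arange(28).reshape(14, 2),
            index=[f"h{i}r{r}" for i in range(7) for r in range(2)],
            columns=["f1", "f2"],
        )
        hosts = {f"h{i}r{r}": f"h{i}" for i in range(7) for r in range(2)}
        return FunctionTable(df, sample_to_host=hosts)

    def test_one_sample_deterministic_and_relabeled(self):
        t = self._two_sample_table()
        a = one_sample_per_species(t, seed=3)
        b = one_sample_per_species(t, seed=3)
        assert a.counts.equals(b.counts)
        assert sorted(a.sample_ids) == [f"h{i}" for i in range(7)]

    def test_single_sampled_hosts_unchanged(self, small_table):
        t = small_table.subset(["s1", "s3"])
        out = one_sample_per_species(t, seed=0)
        assert sorted(out.sample_ids) == ["hA", "hB"]
        assert (out.counts.loc["hA"].to_numpy() == t.counts.loc["s1"].to_numpy()).all()

    def test_choice_uniform_over_seeds(self):
        t = self._two_sample_table()
        picks = np.zeros(7)
        n_seeds = 4000
        for s in range(n_seeds):
            out = one_sample_per_species(t, seed=s)
            for i in range(7):
                # counts row identifies which replicate was chosen
                if out.counts.loc[f"h{i}", "f1"] == t.counts.loc[f"h{i}r1", "f1"]:
                    picks[i] += 1
        freq = picks / n_seeds
        assert (np.abs(freq - 0.5) < 0.03).all()

    def test_selection_rules_and_scaled_matrix(self):
        results = [
            SignalResult("f1", K=2.0, mse_ratio_obs=2, mse_ratio_exp=1, pic_variance_obs=1, p_value=0.01),
            SignalResult("f2", K=0.5, mse_ratio_obs=1, mse_ratio_exp=2, pic_variance_obs=1, p_value=0.8),
            SignalResult("f3", K=3.0, mse_ratio_obs=3, mse_ratio_exp=1, pic_variance_obs=1, p_value=0.04),
        ]
        ab = pd.DataFrame(
            {"f1": [0.1, 0.4], "f2": [0.2, 0.2], "f3": [0.5, 0.25]}, index=["h1", "h2"]
        )
        sel, mat = select_signal_functions(results, alpha=0.05, abundance=ab)
        assert [r.function_id for r in sel] == ["f3", "f1"]  # K descending
        assert np.allclose(mat.max(axis=0), 1.0)
        none_sel, _ = select_signal_functions(
            [SignalResult("f", 1, 1, 1, 1, p_value=1.0)], alpha=0.05
        )
        assert none_sel == []
        all_sel, _ = select_signal_functions(results, alpha=1.0)
        assert len(all_sel) == 3

    def test_signal_all_order_independent_and_table(self):
        tree = simulate_tree(6, 1.0, seed=8)
        rng = np.random.default_rng(1)
        hosts = sorted(l.taxon.label for l in tree.leaf_node_iter())
        tbl = pd.DataFrame(rng.random((6, 3)), index=hosts, columns=["a", "b", "c"])
        r1 = signal_all(tree, tbl, n_rand=99, seed=5)
        r2 = signal_all(tree, tbl[["c", "a", "b"]], n_rand=99, seed=5)
        p1 = {r.function_id: r.p_value for r in r1}
        p2 = {r.function_id: r.p_value for r in r2}
        assert p1 == p2
        df = signal_table(r1)
        assert set(df.columns) >= {"K", "p_value", "bh_q"}
        assert ((df["bh_q"] >= df["p_value"]) | np.isclose(df["bh_q"], df["p_value"])).all()
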