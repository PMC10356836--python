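import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermodiv.bisse import RateParams
from thermodiv.datasets import SimBisseConfig, simulate_bisse_tree
from thermodiv.diversity import (alpha_diversity, blomberg_k,
                                 community_mean_breadth, env_preference_trait,
                                 levins_breadth, mntd, nti, species_breadths,
                                 vcv_matrix)
from thermodiv.trees import patristic_matrix

from .conftest import newick


class TestAlphaDiversity:
    @pytest.mark.parametrize("counts,richness,invsimp,shannon", [
        ([1] * 10, 10, 10.0, np.log(10)),
        ([7], 1, 1.0, 0.0),
        ([1, 1, 2], 3, 1 / 0.375, None),
    ])
    def test_closed_forms(self, counts, richness, invsimp, shannon):
        table = pd.DataFrame({"s": counts},
                             index=[f"sp{i}" for i in range(len(counts))])
        prof = alpha_diversity(table)
        assert prof.loc["s", "richness"] == richness
        assert prof.loc["s", "inverse_simpson"] == pytest.approx(invsimp)
        if shannon is not None:
            assert prof.loc["s", "shannon"] == pytest.approx(shannon)

    def test_all_zero_sample_flagged(self):
        table = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="no counts"):
            prof = alpha_diversity(table)
        assert np.isnan(prof.loc["s2", "richness"])

    @given(st.lists(st.integers(1, 50), min_size=2, max_size=12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_inverse_simpson_bounded_by_richness(self, counts):
        table = pd.DataFrame({"s": counts},
                             index=[f"sp{i}" for i in range(len(counts))])
        prof = alpha_diversity(table)
        assert 1.0 <= prof.loc["s", "inverse_simpson"] \
            <= prof.loc["s", "richness"] + 1e-9
        if len(set(counts)) == 1:
            assert prof.loc["s", "inverse_simpson"] == pytest.approx(
                prof.loc["s", "richness"])


class TestMNTD:
    def test_hand_values_three_tip_tree(self, toy_tree):
        pdm = patristic_matrix(toy_tree)
        assert mntd(pdm, ["A", "B"]) == pytest.approx(2.0)
        assert mntd(pdm, ["A", "B", "C"]) == pytest.approx((2 + 2 + 4) / 3)

    def test_star_tree_symmetry(self):
        pdm = patristic_matrix(newick("(A:1.5,B:1.5,C:1.5,D:1.5,E:1.5);"))
        for taxa in (["A", "B"], ["A", "C", "E"], ["B", "C", "D", "E"]):
            assert mntd(pdm, taxa) == pytest.approx(3.0)

    def test_single_taxon_undefined(self, toy_tree):
        with pytest.raises(ValueError):
            mntd(patristic_matrix(toy_tree), ["A"])

    def test_pruning_nonpool_tips_leaves_values_unchanged(self):
        from thermodiv.trees import prune_to_taxa
        tree = newick("(((A:1,B:1):1,C:2):1,(D:0.5,E:0.5):2.5);")
        pool = ["A", "B", "C"]
        full = mntd(patristic_matrix(tree), pool)
        pruned = mntd(patristic_matrix(prune_to_taxa(tree, pool)), pool)
        assert full == pytest.approx(pruned)


class TestNTI:
    def test_sample_equals_pool_degenerate(self, toy_tree):
        val, degenerate = nti(patristic_matrix(toy_tree), ["A", "B", "C"],
                              n_null=25, seed=0)
        assert degenerate
        assert val == 0.0

    def test_exhaustive_four_tip_null(self):
        # 2-taxon samples on 4 tips: the null has C(4,2)=6 equally likely
        # MNTD values; compare against their exact mean/sd
        tree = newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")
        labels, D = patristic_matrix(tree)
        i = {l: k for k, l in enumerate(labels)}
        import itertools
        pairs = list(itertools.combinations(labels, 2))
        vals = np.array([D[i[a], i[b]] for a, b in pairs])
        exact_mean, exact_sd = vals.mean(), vals.std(ddof=0)
        obs = D[i["A"], i["C"]]
        exact_nti = -(obs - exact_mean) / exact_sd
        est, degenerate = nti((labels, D), ["A", "C"], n_null=4000, seed=5)
        assert not degenerate
        assert est == pytest.approx(exact_nti, abs=0.2)

    def test_sign_convention_clustered_positive(self):
        # two cherries far apart: a within-cherry sample is clustered
        tree = newick("((A:0.1,B:0.1):5,(C:0.1,D:0.1):5);")
        val, _ = nti(patristic_matrix(tree), ["A", "B"], n_null=999, seed=0)
        assert val > 0


class TestLevins:
    @pytest.mark.parametrize("p,expect", [
        ([1, 0, 0, 0, 0, 0, 0, 0], 1.0),
        ([1] * 8, 8.0),
        ([0.5, 0.5, 0, 0, 0, 0, 0, 0], 2.0),
    ])
    def test_closed_forms(self, p, expect):
        assert levins_breadth(p) == pytest.approx(expect)

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=8),
           st.floats(0.1, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, c):
        a = levins_breadth(x)
        b = levins_breadth([v * c for v in x])
        assert a == pytest.approx(b, rel=1e-9)

    def test_species_and_community_breadths(self, default_community):
        table, meta, truth = default_community
        b = species_breadths(table, meta)
        assert ((b >= 1 - 1e-9) & (b <= 8 + 1e-9)).all()
        spec = truth.index[truth["planted_class"] == "specialist"]
        assert b.loc[b.index.intersection(spec)].max() == pytest.approx(1.0)
        comm = community_mean_breadth(table, meta)
        assert comm.notna().all()


class TestEnvPreference:
    def test_single_group_preference(self):
        meta = pd.DataFrame({"sample_id": ["a", "b"], "group": ["G1", "G8"],
                             "temperature_C": [80.0, 54.8],
                             "replicate": [1, 1]})
        table = pd.DataFrame({"a": [4, 3], "b": [0, 3]}, index=["hot", "mix"])
        trait = env_preference_trait(table, meta)
        assert trait.loc["hot"] == pytest.approx(80.0)
        assert trait.loc["mix"] == pytest.approx((80.0 + 54.8) / 2)


class TestBlombergK:
    def test_constant_trait_is_zero(self, yule_tree40):
        tree, _ = yule_tree40
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        K, p = blomberg_k(tree, {l: 3.14 for l in labels}, n_perm=9, seed=0)
        assert K == 0.0

    def test_brownian_motion_mean_near_one(self, yule_tree40):
        tree, _ = yule_tree40
        labels, C = vcv_matrix(tree)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(17)
        ks = []
        for rep in range(60):
            x = L @ rng.standard_normal(len(labels))
            K, _ = blomberg_k(tree, dict(zip(labels, x)), n_perm=19,
                              seed=rep)
            ks.append(K)
        assert abs(np.mean(ks) - 1.0) < 0.25

    def test_strong_signal_detected(self, yule_tree40):
        # trait equal to a BM draw has low contrast variance vs permutations
        tree, _ = yule_tree40
        labels, C = vcv_matrix(tree)
        L = np.linalg.cholesky(C)
        x = L @ np.random.default_rng(3).standard_normal(len(labels))
        _, p = blomberg_k(tree, dict(zip(labels, x)), n_perm=199, seed=0)
        assert p < 0.05

    def test_too_few_tips_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="4 tips"):
            blomberg_k(toy_tree, {"A": 1, "B": 2, "C": 3})
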