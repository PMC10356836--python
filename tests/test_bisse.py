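import numpy as np
import pytest
from scipy.linalg import expm

from thermodiv.bisse import (BisseModel, RateParams, bisse_loglik,
                             compare_fits, fit_bisse, per_group_bisse,
                             starting_point)
from thermodiv.datasets import (SimBisseConfig, SimCommunityConfig,
                                generate_community, simulate_bisse_tree)
from thermodiv.trees import to_arrays

from .conftest import newick, rng_seeds

ALL0 = {"A": 0, "B": 0, "C": 0}


def factorization_oracle(tree, states, lam, mu, q):
    """Independent likelihood for state-independent rates: closed-form
    birth-death flow along branches times a two-state Markov pruning with
    matrix exponentials, flat root weights, no survival conditioning."""
    arr = to_arrays(tree)
    n = arr.n_tips
    d = arr.depths()
    r = lam - mu

    def lnD(t):
        if mu == 0:
            return -lam * t
        return r * t + 2 * np.log(abs(lam - mu)) \
            - 2 * np.log(abs(lam * np.exp(r * t) - mu))

    lnl = (n - 1) * np.log(lam)
    for j in range(n - 1):
        node = n + j
        for c in (arr.left[j], arr.right[j]):
            lnl += lnD(d[node]) - lnD(d[c])
    L = np.zeros((arr.n_nodes, 2))
    for i, lab in enumerate(arr.tip_labels):
        L[i, states[lab]] = 1.0
    Q = np.array([[-q, q], [q, -q]])
    logs = 0.0
    for j in range(n - 1):
        node = n + j
        vals = np.ones(2)
        for c in (arr.left[j], arr.right[j]):
            P = expm(Q * arr.blen[c])
            vals = vals * (P @ L[c])
        s = vals.sum()
        L[node] = vals / s
        logs += np.log(s)
    return lnl + logs + np.log(0.5 * L[-1].sum())


class TestLoglik:
    def test_hand_integrated_three_tip_case(self, toy_tree):
        # E = 0 linearizes the ODEs: D decays as e^{-t} per lineage and each
        # node contributes lambda, giving exactly e^{-5} at the root
        lnl = bisse_loglik(toy_tree, ALL0, RateParams(1, 1, 0, 0, 0, 0),
                           root_mode="obs", condition_survival=False)
        assert lnl == pytest.approx(-5.0, abs=1e-8)

    def test_child_order_symmetry(self):
        p = RateParams(0.9, 1.4, 0.2, 0.1, 0.3, 0.4)
        st = {"A": 0, "B": 1, "C": 0}
        a = bisse_loglik(newick("((A:1,B:1):1,C:2);"), st, p)
        b = bisse_loglik(newick("(C:2,(B:1,A:1):1);"), st, p)
        assert a == pytest.approx(b, abs=1e-10)

    def test_factorization_oracle_random_trees(self):
        rng = np.random.default_rng(101)
        for seed in rng_seeds(6, 55):
            n = int(rng.integers(8, 51))
            lam = rng.uniform(0.5, 1.5)
            mu = rng.uniform(0.0, 0.3)
            q = rng.uniform(0.05, 0.5)
            tree, states = simulate_bisse_tree(SimBisseConfig(
                rates=RateParams(lam, lam, mu, mu, q, q),
                n_tips_target=n, seed=int(seed)))
            ours = bisse_loglik(tree, states,
                                RateParams(lam, lam, mu, mu, q, q),
                                root_mode="flat", condition_survival=False)
            ref = factorization_oracle(tree, states, lam, mu, q)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_mesh_refinement_converged(self, yule_tree40):
        tree, states = yule_tree40
        p = RateParams(0.8, 1.1, 0.15, 0.05, 0.2, 0.1)
        st = {k: v for k, v in states.items()}
        # give the states some variety
        for i, k in enumerate(st):
            st[k] = i % 2
        a = bisse_loglik(tree, st, p, mesh=100)
        b = bisse_loglik(tree, st, p, mesh=200)
        assert abs(a - b) < 1e-6

    def test_smooth_in_each_rate(self, toy_tree):
        base = np.array([1.0, 1.2, 0.1, 0.2, 0.3, 0.4])
        st = {"A": 0, "B": 1, "C": 0}
        for i in range(6):
            grid = []
            for eps in (-1e-4, 0.0, 1e-4):
                v = base.copy()
                v[i] += eps
                grid.append(bisse_loglik(toy_tree, st,
                                         RateParams.from_array(v)))
            # second difference of a smooth function stays tiny
            assert abs(grid[0] - 2 * grid[1] + grid[2]) < 1e-4

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bisse_loglik(newick("(A:1,B:1,C:1);"),
                         {"A": 0, "B": 0, "C": 1},
                         RateParams(1, 1, 0, 0, 0.1, 0.1))


class TestStartingPoint:
    def test_yule_mle_oracle(self):
        # pure-birth MLE: lambda_hat = (n - 2) / total branch length
        tree, _ = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.5, 0.5, 0, 0, 0, 0), n_tips_target=200,
            seed=8))
        arr = to_arrays(tree)
        expect = (arr.n_tips - 2) / arr.blen.sum()
        sp = starting_point(tree)
        assert sp.lambda0 == pytest.approx(expect, rel=0.02)
        assert sp.mu0 == pytest.approx(0.0, abs=0.01 * expect)
        assert sp.q01 == pytest.approx(sp.lambda0 / 10)
        assert sp.q01 == sp.q10

    def test_deterministic(self, yule_tree40):
        tree, _ = yule_tree40
        assert starting_point(tree) == starting_point(tree)


class TestFit:
    def test_nested_models_loglik_order(self):
        tree, states = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.3, 0.3, 0.05, 0.05, 0.1, 0.1),
            n_tips_target=60, seed=21))
        fc = fit_bisse(tree, states, constrained=True, n_restarts=1,
                       random_state=0)
        fu = fit_bisse(tree, states, constrained=False, start=fc.params,
                       n_restarts=1, random_state=0)
        assert fc.params.lambda0 == fc.params.lambda1
        assert fc.params.mu0 == fc.params.mu1
        assert fu.loglik >= fc.loglik - 1e-6

    def test_single_state_tips_fit_completes(self):
        tree, states = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.5, 0.5, 0, 0, 0, 0), n_tips_target=25,
            seed=2))
        fit = fit_bisse(tree, states, constrained=False, n_restarts=1,
                        random_state=0)
        assert np.isfinite(fit.loglik)
        # no transitions observed: at least one transition rate collapses
        assert min(fit.params.q01, fit.params.q10) < 1e-3

    def test_estimator_interface(self):
        tree, states = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.3, 0.3, 0.02, 0.02, 0.1, 0.1),
            n_tips_target=40, seed=33))
        model = BisseModel(n_restarts=1, random_state=0)
        assert model.get_params()["root_mode"] == "obs"
        model.fit(tree, states)
        assert model.loglik_ == pytest.approx(
            model.score(tree, states), abs=1e-6)
        assert model.n_tips_ >= 40


class TestCompare:
    def test_identical_fits_give_p_one(self):
        tree, states = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.4, 0.4, 0.05, 0.05, 0.1, 0.1),
            n_tips_target=30, seed=12))
        fc = fit_bisse(tree, states, constrained=True, n_restarts=1,
                       random_state=0)
        from dataclasses import replace
        fu = replace(fc, constrained=False)
        cmp_ = compare_fits(fc, fu)
        assert cmp_.statistic == 0.0
        assert cmp_.pvalue == 1.0

    def test_wrong_order_rejected(self):
        tree, states = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.4, 0.4, 0.05, 0.05, 0.1, 0.1),
            n_tips_target=30, seed=12))
        fc = fit_bisse(tree, states, constrained=True, n_restarts=1,
                       random_state=0)
        with pytest.raises(ValueError):
            compare_fits(fc, fc)


class TestPerGroup:
    def test_schema_and_skips(self):
        cfg = SimCommunityConfig(seed=77, n_specialists_per_group=4,
                                 n_generalists=12)
        table, meta, truth = generate_community(cfg)
        # unified tree over all species, labels straight from the truth
        tree, _ = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.5, 0.5, 0, 0, 0, 0),
            n_tips_target=len(table), seed=5))
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        rename = dict(zip(tips, table.index))
        for lf in tree.leaf_node_iter():
            lf.taxon.label = rename[lf.taxon.label]
        labels = truth["planted_class"].map(
            {"specialist": "sensitive", "generalist": "resistant"})
        rates, fits = per_group_bisse(tree, labels, table, meta,
                                      min_tips=10, n_restarts=1,
                                      random_state=0)
        assert list(rates.columns[:8]) == [
            "group", "temperature_C", "lambda_Ts", "lambda_Tr", "mu_Ts",
            "mu_Tr", "t_Ts_Tr", "t_Tr_Ts"]
        assert len(rates) == 8
        done = rates[rates["skipped_reason"] == ""]
        assert len(done) == len(fits) > 0
        assert (done["lnL_u"] >= done["lnL_c"] - 1e-6).all()

    def test_single_state_group_skipped(self):
        cfg = SimCommunityConfig(seed=78, n_specialists_per_group=12,
                                 n_generalists=0)
        table, meta, truth = generate_community(cfg)
        tree, _ = simulate_bisse_tree(SimBisseConfig(
            rates=RateParams(0.5, 0.5, 0, 0, 0, 0),
            n_tips_target=len(table), seed=5))
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        rename = dict(zip(tips, table.index))
        for lf in tree.leaf_node_iter():
            lf.taxon.label = rename[lf.taxon.label]
        labels = truth["planted_class"].map({"specialist": "sensitive"})
        rates, fits = per_group_bisse(tree, labels, table, meta,
                                      random_state=0)
        assert (rates["skipped_reason"] == "single state").all()
        assert fits == {}
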