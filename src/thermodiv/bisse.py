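"""Binary-state speciation–extinction (BiSSE) model fitting.

State 0 is the thermal-niche specialist ("T-sensitive") state and state 1 the
generalist ("T-resistant") state throughout the package.  The model assigns
each state its own speciation rate (lambda), extinction rate (mu) and
transition rate (q01: 0 -> 1, q10: 1 -> 0), and the likelihood of a rooted
binary tree with binary tip states is computed by the classic pruning ODEs
(see :mod:`thermodiv._engine`).

Fitting follows a two-round protocol: a constrained round with
lambda0 = lambda1 and mu0 = mu1, then a fully unconstrained round; a
likelihood-ratio test with two degrees of freedom compares them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from . import trees as _trees
from ._engine import bisse_lnl_arrays, root_code

__all__ = [
    "RateParams",
    "BisseFit",
    "ModelComparison",
    "BisseModel",
    "bisse_loglik",
    "starting_point",
    "fit_bisse",
    "compare_fits",
    "per_group_bisse",
    "bd_loglik",
]

DEFAULT_MESH = 100.0  # RK4 steps per unit of (total event rate x time)


@dataclass(frozen=True)
class RateParams:
    """The six BiSSE rates, per lineage per unit branch length."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"rate {name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda0, self.lambda1, self.mu0, self.mu1,
                         self.q01, self.q10])

    def as_dict(self) -> dict:
        return {"lambda0": self.lambda0, "lambda1": self.lambda1,
                "mu0": self.mu0, "mu1": self.mu1,
                "q01": self.q01, "q10": self.q10}

    @classmethod
    def from_array(cls, a) -> "RateParams":
        return cls(*[float(x) for x in a])


@dataclass
class BisseFit:
    params: RateParams
    loglik: float
    constrained: bool
    converged: bool
    n_tips: int
    root_mode: str
    condition_survival: bool
    n_restarts: int = 1
    optimizer_messages: list = field(default_factory=list)


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested constrained/unconstrained fits."""

    statistic: float
    df: int
    pvalue: float
    verdict: str


def _prepare(tree, states):
    """Tree arrays + int8 state vector aligned to tip order."""
    arr = tree if isinstance(tree, _trees.TreeArrays) else _trees.to_arrays(tree)
    if hasattr(states, "to_dict"):
        states = states.to_dict()
    st = np.empty(arr.n_tips, dtype=np.int8)
    for i, lab in enumerate(arr.tip_labels):
        if lab not in states:
            raise KeyError(f"no state for tip {lab!r}")
        s = int(states[lab])
        if s not in (0, 1):
            raise ValueError(f"state of {lab!r} must be 0 or 1, got {s}")
        st[i] = s
    return arr, st


def bisse_loglik(tree, states, params: RateParams, root_mode: str = "obs",
                 condition_survival: bool = True,
                 mesh: float = DEFAULT_MESH) -> float:
    """BiSSE log-likelihood of a rooted binary tree with binary tip states.

    Parameters
    ----------
    tree : dendropy.Tree or TreeArrays
        Rooted, strictly binary; polytomies and negative branch lengths raise.
    states : mapping
        Tip label -> 0/1.
    params : RateParams
    root_mode : {"obs", "flat", "equilibrium", "fixed0", "fixed1"}
        Root-state weighting; "obs" weights each state by its own D value.
    condition_survival : bool
        Condition the likelihood on both root lineages surviving.
    mesh : float
        Integration refinement (RK4 steps per unit of rate x time); doubling
        it is the convergence check.
    """
    arr, st = _prepare(tree, states)
    a = params.as_array()
    lnl = bisse_lnl_arrays(arr.left, arr.right, arr.blen, st,
                           a[0], a[1], a[2], a[3], a[4], a[5],
                           root_code(root_mode), condition_survival, mesh)
    if not np.isfinite(lnl):
        raise FloatingPointError(
            "BiSSE likelihood under/overflowed beyond rescue for "
            f"params {params}")
    return float(lnl)


# ---------------------------------------------------------------------------
# constant-rate birth–death likelihood (closed form) for the heuristic start
# ---------------------------------------------------------------------------

def bd_loglik(tree, lam: float, mu: float,
              condition_survival: bool = True) -> float:
    """State-independent birth–death log-likelihood (closed form).

    Uses per-branch flow factors D(t) = e^{rt}(lam-mu)^2/(lam e^{rt} - mu)^2
    with r = lam - mu and E(0) = 0, a factor lam per internal node, and the
    same survival conditioning as the BiSSE likelihood.
    """
    arr = tree if isinstance(tree, _trees.TreeArrays) else _trees.to_arrays(tree)
    if lam <= 0:
        return -np.inf
    depths = arr.depths()
    r = lam - mu

    def ln_d(t):
        if abs(r) < 1e-12 * lam:
            return -2.0 * np.log1p(lam * t)
        # ln(lam e^{rt} - mu) computed overflow-free via e^{-rt} when rt > 0
        rt = r * t
        if rt > 0:
            ln_denom = rt + np.log(abs(lam - mu * np.exp(-rt)))
        else:
            ln_denom = np.log(abs(lam * np.exp(rt) - mu))
        return rt + 2.0 * np.log(abs(lam - mu)) - 2.0 * ln_denom

    lnl = 0.0
    root = arr.n_nodes - 1
    for j in range(arr.n_tips - 1):
        node = arr.n_tips + j
        for c in (arr.left[j], arr.right[j]):
            lnl += ln_d(depths[node]) - ln_d(depths[c])
    lnl += (arr.n_tips - 1) * np.log(lam)
    if condition_survival:
        T = depths[root]
        if abs(r) < 1e-12 * lam:
            E = lam * T / (1.0 + lam * T) if mu > 0 else 0.0
        else:
            ert = np.exp(-r * T) if r * T > 0 else None
            if ert is not None:
                E = mu * (1.0 - ert) / (lam - mu * ert)
            else:
                E = mu * (np.exp(r * T) - 1.0) / (lam * np.exp(r * T) - mu)
        lnl -= np.log(lam) + 2.0 * np.log1p(-min(E, 1 - 1e-12))
    return float(lnl)


def starting_point(tree) -> RateParams:
    """Heuristic BiSSE starting rates from a state-independent birth–death fit.

    Maximizes the closed-form birth–death likelihood over (lambda, mu) and
    returns lambda0 = lambda1 = lam_hat, mu0 = mu1 = mu_hat,
    q01 = q10 = lam_hat / 10.
    """
    arr = tree if isinstance(tree, _trees.TreeArrays) else _trees.to_arrays(tree)
    if arr.n_tips < 3:
        raise ValueError("need at least 3 tips")
    # crude initial lambda: Yule estimate (n-2) / total branch length
    total = arr.blen.sum()
    lam0 = max((arr.n_tips - 2) / total, 1e-6) if total > 0 else 1.0

    def nll(x):
        lam = np.exp(x[0])
        mu = lam * x[1]
        return -bd_loglik(arr, lam, mu)

    res = optimize.minimize(nll, x0=np.array([np.log(lam0), 0.1]),
                            method="L-BFGS-B",
                            bounds=[(np.log(lam0) - 7, np.log(lam0) + 7),
                                    (0.0, 0.95)])
    lam = float(np.exp(res.x[0]))
    mu = float(lam * res.x[1])
    return RateParams(lam, lam, mu, mu, lam / 10.0, lam / 10.0)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _expand(free: np.ndarray, constrained: bool) -> np.ndarray:
    if constrained:
        lam, mu, q01, q10 = free
        return np.array([lam, lam, mu, mu, q01, q10])
    return free


def fit_bisse(tree, states, constrained: bool = False,
              start: RateParams | None = None,
              bounds: tuple = (1e-8, 1e3),
              root_mode: str = "obs", condition_survival: bool = True,
              n_restarts: int = 3, mesh: float = DEFAULT_MESH,
              random_state=None) -> BisseFit:
    """Bounded ML fit of the BiSSE rates (log-scale L-BFGS-B, jittered restarts).

    ``constrained=True`` enforces lambda0 = lambda1 and mu0 = mu1 (the first
    round of the two-round protocol); the transition rates are always free.
    """
    arr, st = _prepare(tree, states)
    rng = np.random.default_rng(random_state)
    if start is None:
        start = starting_point(arr)
    rc = root_code(root_mode)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def nll(x):
        p = _expand(np.exp(x), constrained)
        lnl = bisse_lnl_arrays(arr.left, arr.right, arr.blen, st,
                               p[0], p[1], p[2], p[3], p[4], p[5],
                               rc, condition_survival, mesh)
        if not np.isfinite(lnl):
            return 1e10
        return -lnl

    s = start.as_array()
    if constrained:
        x0_base = np.log(np.clip(
            np.array([s[0], s[2], s[4], s[5]]), bounds[0], bounds[1]))
    else:
        x0_base = np.log(np.clip(s, bounds[0], bounds[1]))
    x0_base = np.clip(x0_base, lo, hi)

    best = None
    messages = []
    for k in range(max(1, n_restarts)):
        x0 = x0_base if k == 0 else np.clip(
            x0_base + rng.uniform(-1.0, 1.0, size=x0_base.size), lo, hi)
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(lo, hi)] * x0_base.size)
        messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
    params = RateParams.from_array(_expand(np.exp(best.x), constrained))
    loglik = -float(best.fun)
    converged = bool(best.success) and loglik > -1e9
    if not converged:
        warnings.warn("BiSSE optimization did not converge cleanly: "
                      + messages[-1], RuntimeWarning)
    return BisseFit(params=params, loglik=loglik, constrained=constrained,
                    converged=converged, n_tips=arr.n_tips,
                    root_mode=root_mode, condition_survival=condition_survival,
                    n_restarts=n_restarts, optimizer_messages=messages)


def compare_fits(constrained: BisseFit, unconstrained: BisseFit,
                 tol: float = 1e-3) -> ModelComparison:
    """Likelihood-ratio test of the unconstrained against the constrained fit.

    Two equality constraints are released, so the statistic is referred to a
    chi-squared distribution with 2 degrees of freedom.
    """
    if not constrained.constrained or unconstrained.constrained:
        raise ValueError("pass (constrained, unconstrained) fits in that order")
    stat = 2.0 * (unconstrained.loglik - constrained.loglik)
    if stat < -tol * max(1.0, abs(constrained.loglik)):
        raise RuntimeError(
            f"unconstrained logLik {unconstrained.loglik:.6f} below "
            f"constrained {constrained.loglik:.6f}: optimizer failure")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=2)) if stat > 0 else 1.0
    verdict = ("state-dependent rates supported" if p < 0.05
               else "no evidence for state-dependent rates")
    return ModelComparison(statistic=float(stat), df=2, pvalue=p,
                           verdict=verdict)


class BisseModel(BaseEstimator):
    """Maximum-likelihood BiSSE estimator (scikit-learn style).

    Parameters
    ----------
    constrained : bool, default False
        Enforce equal speciation and equal extinction rates across states.
    root_mode : str, default "obs"
    condition_survival : bool, default True
    n_restarts : int, default 3
        Jittered optimizer restarts; the best likelihood is kept.
    mesh : float
        Integration refinement of the pruning ODEs.
    ultrametrize : bool, default True
        Extend terminal branches (tolerance 1% of depth) before fitting.
    random_state : int or None

    Attributes
    ----------
    params_ : RateParams
    loglik_ : float
    converged_ : bool
    n_tips_ : int
    fit_ : BisseFit
    """

    def __init__(self, constrained=False, root_mode="obs",
                 condition_survival=True, n_restarts=3, mesh=DEFAULT_MESH,
                 bounds=(1e-8, 1e3), ultrametrize=True, random_state=None):
        self.constrained = constrained
        self.root_mode = root_mode
        self.condition_survival = condition_survival
        self.n_restarts = n_restarts
        self.mesh = mesh
        self.bounds = bounds
        self.ultrametrize = ultrametrize
        self.random_state = random_state

    def fit(self, tree, states):
        if self.ultrametrize and not isinstance(tree, _trees.TreeArrays):
            tree = _trees.make_ultrametric(tree, rel_tol=0.01)
        self.fit_ = fit_bisse(
            tree, states, constrained=self.constrained,
            bounds=self.bounds, root_mode=self.root_mode,
            condition_survival=self.condition_survival,
            n_restarts=self.n_restarts, mesh=self.mesh,
            random_state=self.random_state)
        self.params_ = self.fit_.params
        self.loglik_ = self.fit_.loglik
        self.converged_ = self.fit_.converged
        self.n_tips_ = self.fit_.n_tips
        return self

    def score(self, tree, states):
        """Log-likelihood of data under the fitted rates."""
        return bisse_loglik(tree, states, self.params_,
                            root_mode=self.root_mode,
                            condition_survival=self.condition_survival,
                            mesh=self.mesh)


# ---------------------------------------------------------------------------
# per-temperature-group orchestration
# ---------------------------------------------------------------------------

RATE_COLUMNS = ["lambda_Ts", "lambda_Tr", "mu_Ts", "mu_Tr", "t_Ts_Tr", "t_Tr_Ts"]


def per_group_bisse(tree, labels, table: pd.DataFrame, meta: pd.DataFrame,
                    min_count: int = 1, min_tips: int = 10,
                    root_mode: str = "obs", condition_survival: bool = True,
                    n_restarts: int = 3, mesh: float = DEFAULT_MESH,
                    random_state=None):
    """Two-round BiSSE fits on each temperature group's pruned tree.

    For every group, the unified tree is pruned to the classified
    (sensitive/resistant) species detected in that group, the constrained and
    unconstrained rounds are fitted, and the two are compared by LRT.  Groups
    with fewer than ``min_tips`` usable tips or a single state are skipped
    with a recorded reason.

    Parameters
    ----------
    tree : dendropy.Tree
        Unified phylogeny over the classified species.
    labels : mapping or Series
        Species -> {"sensitive", "resistant", "other"}.
    table, meta : DataFrame
        Counts (species x samples) and sample metadata with ``sample_id``,
        ``group`` and ``temperature_C`` columns.

    Returns
    -------
    rates : DataFrame, one row per group (skipped groups included)
    fits : dict group -> (BisseFit constrained, BisseFit unconstrained,
        ModelComparison) for non-skipped groups
    """
    if hasattr(labels, "to_dict"):
        labels = labels.to_dict()
    tree = _trees.make_ultrametric(tree, rel_tol=0.01)
    tip_set = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ss = np.random.SeedSequence(random_state).spawn(
        meta["group"].nunique())
    rows = []
    fits = {}
    groups = (meta[["group", "temperature_C"]].drop_duplicates()
              .sort_values("temperature_C", ascending=False))
    for gi, (_, grow) in enumerate(groups.iterrows()):
        group, temp = grow["group"], float(grow["temperature_C"])
        samples = meta.loc[meta["group"] == group, "sample_id"]
        detected = table.index[(table[samples] >= min_count).any(axis=1)]
        usable, states = [], {}
        for sp in detected:
            lab = labels.get(sp, "other")
            if lab == "sensitive" and sp in tip_set:
                usable.append(sp)
                states[sp] = 0
            elif lab == "resistant" and sp in tip_set:
                usable.append(sp)
                states[sp] = 1
        row = {"group": group, "temperature_C": temp, "n_tips": len(usable)}
        n_states = len({states[s] for s in usable})
        if len(usable) < min_tips:
            row["skipped_reason"] = f"only {len(usable)} usable tips"
        elif n_states < 2:
            row["skipped_reason"] = "single state"
        else:
            sub = _trees.prune_to_taxa(tree, usable)
            seed = int(ss[gi].generate_state(1)[0] % (2 ** 31))
            kw = dict(root_mode=root_mode,
                      condition_survival=condition_survival,
                      n_restarts=n_restarts, mesh=mesh, random_state=seed)
            fit_c = fit_bisse(sub, states, constrained=True, **kw)
            fit_u = fit_bisse(sub, states, constrained=False,
                              start=fit_c.params, **kw)
            if fit_u.loglik < fit_c.loglik:  # nesting guard
                fit_u = replace(fit_c, constrained=False)
            cmp_ = compare_fits(fit_c, fit_u)
            p = fit_u.params
            row.update({"lambda_Ts": p.lambda0, "lambda_Tr": p.lambda1,
                        "mu_Ts": p.mu0, "mu_Tr": p.mu1,
                        "t_Ts_Tr": p.q01, "t_Tr_Ts": p.q10,
                        "lnL_c": fit_c.loglik, "lnL_u": fit_u.loglik,
                        "LRT": cmp_.statistic, "p": cmp_.pvalue,
                        "skipped_reason": ""})
            fits[group] = (fit_c, fit_u, cmp_)
        rows.append(row)
    cols = ["group", "temperature_C"] + RATE_COLUMNS + [
        "lnL_c", "lnL_u", "LRT", "p", "n_tips", "skipped_reason"]
    rates = pd.DataFrame(rows).reindex(columns=cols)
    return rates, fits
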