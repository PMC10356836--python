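"""Diversification / environmental-filtering indices and Arrhenius scaling.

Under the metabolic theory of ecology a temperature-dependent rate V obeys
V(T) ~ exp(-E / (k T)) with T in kelvin, k the Boltzmann constant in eV/K and
E the activation energy in electron-volts.  Ordinary least squares of ln V on
1/(k T) therefore estimates E as the negative of the slope.

The two indices summarize fitted binary-state diversification rates:

* diversification potential   DP = lambda + t - mu   (focal state's
  speciation plus a transition term minus its extinction),
* environmental-filtering potential   EP = mu.

The transition term in DP is ambiguous in direction; by default the
transition INTO the focal state is used (transitions add species of that
state), and both orientations are always reported side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .bisse import RateParams

__all__ = [
    "BOLTZMANN_EV",
    "ArrheniusFit",
    "ArrheniusRegression",
    "arrhenius_fit",
    "diversification_potential",
    "environmental_filtering_potential",
    "relative_strength",
    "index_series",
]

BOLTZMANN_EV = 8.617333262e-5  # eV / K


@dataclass
class ArrheniusFit:
    slope: float          # eV (of ln v vs 1/(kT))
    intercept: float
    E: float              # activation energy, eV; E = -slope
    r2: float
    pvalue: float
    n_used: int
    n_dropped: int


def arrhenius_fit(values, temps_C) -> ArrheniusFit:
    """OLS of ln(value) on 1/(k T_K); nonpositive values are dropped.

    Raises ``ValueError`` with fewer than 3 positive points.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(temps_C, dtype=float)
    if v.shape != t.shape:
        raise ValueError("values and temps_C must have the same length")
    ok = np.isfinite(v) & (v > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} nonpositive/undefined values "
                      "from the Arrhenius regression", UserWarning)
    v, t = v[ok], t[ok]
    if v.size < 3:
        raise ValueError(f"need >= 3 positive points, have {v.size}")
    x = 1.0 / (BOLTZMANN_EV * (t + 273.15))
    res = stats.linregress(x, np.log(v))
    return ArrheniusFit(slope=float(res.slope),
                        intercept=float(res.intercept),
                        E=float(-res.slope),
                        r2=float(res.rvalue ** 2),
                        pvalue=float(res.pvalue),
                        n_used=int(v.size), n_dropped=n_dropped)


class ArrheniusRegression(BaseEstimator, RegressorMixin):
    """Arrhenius (metabolic-scaling) regression as an estimator.

    ``fit(temps_C, values)`` regresses ln(values) on 1/(k T).  Fitted
    attributes: ``slope_``, ``intercept_``, ``activation_energy_`` (eV),
    ``r2_``, ``pvalue_``, ``n_used_``, ``n_dropped_``.
    """

    def fit(self, temps_C, values):
        f = arrhenius_fit(values, temps_C)
        self.slope_ = f.slope
        self.intercept_ = f.intercept
        self.activation_energy_ = f.E
        self.r2_ = f.r2
        self.pvalue_ = f.pvalue
        self.n_used_ = f.n_used
        self.n_dropped_ = f.n_dropped
        self.fit_ = f
        return self

    def predict(self, temps_C):
        t = np.asarray(temps_C, dtype=float)
        x = 1.0 / (BOLTZMANN_EV * (t + 273.15))
        return np.exp(self.intercept_ + self.slope_ * x)


def _transition(params: RateParams, focal_state: int, orientation: str):
    if focal_state not in (0, 1):
        raise ValueError("focal_state must be 0 or 1")
    if orientation not in ("in", "out"):
        raise ValueError("orientation must be 'in' or 'out'")
    incoming = params.q10 if focal_state == 0 else params.q01
    outgoing = params.q01 if focal_state == 0 else params.q10
    return incoming if orientation == "in" else outgoing


def diversification_potential(params: RateParams, focal_state: int = 0,
                              orientation: str = "in") -> float:
    """DP = lambda_focal + t - mu_focal.

    ``orientation`` selects the transition term: "in" uses the rate into the
    focal state, "out" the rate out of it.
    """
    lam = params.lambda0 if focal_state == 0 else params.lambda1
    mu = params.mu0 if focal_state == 0 else params.mu1
    return float(lam + _transition(params, focal_state, orientation) - mu)


def environmental_filtering_potential(params: RateParams,
                                      focal_state: int = 1) -> float:
    """EP = mu_focal (extinction as the filtering potential)."""
    return float(params.mu1 if focal_state == 1 else params.mu0)


def relative_strength(dp_values, ep_values, temps_C):
    """RS = DP/EP per group plus its Arrhenius fit (None if infeasible).

    On noiseless inputs the RS fit's slope equals +(E_EP - E_DP), i.e. its
    activation-energy estimate is E_DP - E_EP.
    """
    dp = np.asarray(dp_values, dtype=float)
    ep = np.asarray(ep_values, dtype=float)
    rs = np.where(ep > 0, dp / np.where(ep > 0, ep, np.nan), np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit = arrhenius_fit(rs, temps_C)
    except ValueError:
        fit = None
    return rs, fit


def index_series(rates: pd.DataFrame, sensitive_state: int = 0,
                 orientation: str = "in") -> pd.DataFrame:
    """Per-group DP/EP/RS from a per-group rate table.

    ``rates`` must carry the columns produced by
    :func:`thermodiv.bisse.per_group_bisse`.  DP is computed for the
    sensitive (specialist) state and EP for the resistant (generalist) state,
    with both transition orientations reported.
    """
    rows = []
    for _, r in rates.iterrows():
        if r.get("skipped_reason", "") or pd.isna(r.get("lambda_Ts", np.nan)):
            continue
        p = RateParams(r["lambda_Ts"], r["lambda_Tr"], r["mu_Ts"], r["mu_Tr"],
                       r["t_Ts_Tr"], r["t_Tr_Ts"])
        row = {
            "group": r["group"],
            "temperature_C": r["temperature_C"],
            "temperature_K": r["temperature_C"] + 273.15,
            "DP_in": diversification_potential(p, sensitive_state, "in"),
            "DP_out": diversification_potential(p, sensitive_state, "out"),
            "EP": environmental_filtering_potential(p, 1 - sensitive_state),
        }
        row["DP"] = row["DP_in"] if orientation == "in" else row["DP_out"]
        row["RS"] = row["DP"] / row["EP"] if row["EP"] > 0 else np.nan
        row["orientation"] = orientation
        rows.append(row)
    return pd.DataFrame(rows)
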