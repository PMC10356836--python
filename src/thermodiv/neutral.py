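"""Sloan neutral community model fit.

Under the neutral model, the relative abundance of a species whose
metacommunity mean abundance is p follows a Beta(N m p, N m (1 - p))
distribution in a local community of size N with migration probability m.
A species is detected in a sample when its relative abundance exceeds the
detection limit d = 1/N, so its expected detection frequency is
F(p) = 1 - BetaCDF(d; N m p, N m (1 - p)).  The single free parameter m is
estimated by least squares of observed detection frequencies on F(p); Nm is
the dispersal parameter reported by the model, and R^2 the fit to the
neutral expectation (negative when the model fits worse than the mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["NCMFit", "NeutralCommunityModel", "fit_ncm"]


@dataclass
class NCMFit:
    m: float
    Nm: float
    N: float
    r2: float
    converged: bool
    species: pd.DataFrame      # p, freq_observed, freq_predicted, band
    detection_limit: float


def _predicted_freq(p, N, m, d):
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(d, a, b)


def fit_ncm(table: pd.DataFrame, community_size: float | None = None,
            detection_limit: float | None = None) -> NCMFit:
    """Fit the Sloan neutral model to an abundance table.

    p_i is the mean relative abundance of species i across samples and f_i
    its detection frequency.  N defaults to the mean reads per sample and the
    detection limit to 1/N (both overridable).  The 95% band around the
    predicted frequency is the binomial sampling error at the observed number
    of samples (approximate).
    """
    table = table.loc[(table > 0).any(axis=1)]
    n_sp, n_samples = table.shape
    if n_sp < 10:
        raise ValueError(f"need >= 10 detected species, have {n_sp}")
    if n_samples < 5:
        raise ValueError(f"need >= 5 samples, have {n_samples}")
    rel = table.div(table.sum(axis=0), axis=1)
    p = rel.mean(axis=1).to_numpy()
    f = (table > 0).mean(axis=1).to_numpy()
    N = float(table.sum(axis=0).mean()) if community_size is None \
        else float(community_size)
    d = 1.0 / N if detection_limit is None else float(detection_limit)

    def sse(m):
        return float(np.sum((f - _predicted_freq(p, N, m, d)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(1e-9, 1.0 - 1e-9),
                                   method="bounded")
    m = float(res.x)
    converged = bool(res.success)
    if m < 1e-7 or m > 1.0 - 1e-7:
        converged = False
        warnings.warn("migration estimate at its bound; NCM fit did not "
                      "converge meaningfully", UserWarning)
    pred = _predicted_freq(p, N, m, d)
    ss_res = np.sum((f - pred) ** 2)
    ss_tot = np.sum((f - f.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    half = 1.96 * np.sqrt(np.clip(pred * (1 - pred), 0, None) / n_samples)
    species = pd.DataFrame({
        "p": p, "freq_observed": f, "freq_predicted": pred,
        "band_lower": np.clip(pred - half, 0, 1),
        "band_upper": np.clip(pred + half, 0, 1),
    }, index=table.index)
    return NCMFit(m=m, Nm=N * m, N=N, r2=float(r2), converged=converged,
                  species=species, detection_limit=d)


class NeutralCommunityModel(BaseEstimator):
    """Sloan neutral model estimator (scikit-learn style).

    Parameters
    ----------
    community_size : float or None
        N; defaults to the mean reads per sample of the fitted table.
    detection_limit : float or None
        Defaults to 1/N.

    Attributes
    ----------
    m_, Nm_, N_, r2_ : floats
    converged_ : bool
    species_ : DataFrame with per-species p, observed and predicted
        frequencies and the approximate 95% band
    """

    def __init__(self, community_size=None, detection_limit=None):
        self.community_size = community_size
        self.detection_limit = detection_limit

    def fit(self, table, y=None):
        f = fit_ncm(table, community_size=self.community_size,
                    detection_limit=self.detection_limit)
        self.fit_ = f
        self.m_ = f.m
        self.Nm_ = f.Nm
        self.N_ = f.N
        self.r2_ = f.r2
        self.converged_ = f.converged
        self.species_ = f.species
        return self

    def predict(self, p):
        """Predicted detection frequency at mean relative abundance p."""
        return _predicted_freq(np.asarray(p, dtype=float), self.N_, self.m_,
                               self.fit_.detection_limit)
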