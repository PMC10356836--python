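"""Occupancy across temperature groups, its permutation null, and the
specialist/generalist classification.

Occupancy of a species is the number of temperature groups in which it is
detected.  The null asks whether the observed occupancy histogram could arise
if each species' occupied samples were placed at random: per species, the
incidence set (which samples it occupies, size held fixed) is redrawn
uniformly among all samples and group occupancy recomputed.  Occupancy
classes where the observed species count exceeds the permutation expectation
(strict inequality) define the classification: the maximal run of exceedance
classes starting at occupancy 1 marks "sensitive" (specialist) species and
the maximal run ending at the number of groups marks "resistant"
(generalist) species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "OccupancyResult",
    "ClassificationResult",
    "OccupancyClassifier",
    "compute_occupancy",
    "occupancy_null",
    "classify_species",
    "occupancy_sampling_law",
]


@dataclass
class OccupancyResult:
    occupancy: pd.Series          # per-species occupancy (1..G)
    classes: np.ndarray           # occupancy classes 1..G
    observed_hist: np.ndarray     # species counts per class
    expected_hist: np.ndarray     # permutation mean per class
    exceedance: np.ndarray        # observed > expected (strict)
    pvalues: np.ndarray           # upper-tail permutation p per class
    n_perm: int
    null: str


@dataclass
class ClassificationResult:
    labels: pd.Series             # sensitive / resistant / other
    sensitive_classes: tuple      # occupancy classes defining "sensitive"
    resistant_classes: tuple


def _align(table: pd.DataFrame, meta: pd.DataFrame):
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    missing = set(table.columns) - set(meta["sample_id"])
    if missing:
        raise KeyError(f"samples without metadata: {sorted(missing)[:5]}")
    meta = meta.set_index("sample_id").loc[list(table.columns)].reset_index()
    return table, meta


def compute_occupancy(table: pd.DataFrame, meta: pd.DataFrame,
                      min_count: int = 1) -> pd.Series:
    """Number of temperature groups where each species is detected.

    A species is retained iff its total count is >= ``min_count``; it is
    detected in a group iff any of the group's samples has count >=
    ``min_count``.
    """
    if table.shape[0] == 0:
        raise ValueError("abundance table has no species")
    table, meta = _align(table, meta)
    keep = table.sum(axis=1) >= min_count
    if not keep.any():
        raise ValueError("no species retained at this min_count")
    pres = table.loc[keep] >= min_count
    groups = meta.set_index("sample_id")["group"]
    by_group = pres.T.groupby(groups).any().T
    occ = by_group.sum(axis=1).astype(int)
    occ = occ[occ >= 1]
    occ.name = "occupancy"
    return occ


def occupancy_sampling_law(k: int, group_sizes) -> np.ndarray:
    """Exact distribution of groups covered by k samples drawn uniformly
    without replacement.

    ``law[j-1]`` is the probability that the k samples span exactly j of the
    G groups (inclusion–exclusion over group subsets, exact integer
    arithmetic).  This is the single-species law of the "redraw" null.
    """
    sizes = list(group_sizes)
    G = len(sizes)
    S = sum(sizes)
    if not (1 <= k <= S):
        raise ValueError(f"k={k} out of range 1..{S}")
    # ways[m][s]: number of group subsets with m groups totalling s samples
    ways = {(0, 0): 1}
    for n in sizes:
        nxt = dict(ways)
        for (m, s), c in ways.items():
            key = (m + 1, s + n)
            nxt[key] = nxt.get(key, 0) + c
        ways = nxt
    denom = math.comb(S, k)
    law = np.zeros(G)
    for j in range(1, G + 1):
        num = 0
        for (m, s), c in ways.items():
            if m > j:
                continue
            num += c * (-1) ** (j - m) * math.comb(G - m, j - m) \
                * math.comb(s, k)
        law[j - 1] = num / denom
    law = np.clip(law, 0.0, 1.0)
    return law / law.sum()


def _null_redraw(k_per_species, group_sizes, n_perm, rng):
    """Class-count draws (n_perm x G) under the per-species redraw null.

    Species with the same incidence count share the same exact occupancy law,
    so each permutation's class counts are assembled from one multinomial
    draw per distinct incidence count — distributionally identical to
    literally redrawing every species' incidence set.
    """
    G = len(group_sizes)
    counts = np.zeros((n_perm, G), dtype=np.int64)
    ks, nk = np.unique(np.asarray(k_per_species), return_counts=True)
    for k, n_k in zip(ks, nk):
        law = occupancy_sampling_law(int(k), group_sizes)
        counts += rng.multinomial(int(n_k), law, size=n_perm)
    return counts, counts.mean(axis=0)


def _null_fixedfixed(pres: np.ndarray, group_of_sample: np.ndarray,
                     n_perm, rng, n_trades=None):
    """Curveball trades preserving row and column totals of the incidence
    matrix; occupancy histogram recorded after each batch of trades."""
    m = pres.copy()
    n_sp, n_smp = m.shape
    G = group_of_sample.max() + 1
    if n_trades is None:
        n_trades = 5 * n_sp
    counts = np.zeros((n_perm, G), dtype=np.int64)
    for b in range(n_perm):
        for _ in range(n_trades):
            i, j = rng.integers(n_sp), rng.integers(n_sp)
            if i == j:
                continue
            ri, rj = m[i], m[j]
            only_i = np.flatnonzero(ri & ~rj)
            only_j = np.flatnonzero(~ri & rj)
            if only_i.size == 0 or only_j.size == 0:
                continue
            pool = np.concatenate([only_i, only_j])
            rng.shuffle(pool)
            new_i = pool[:only_i.size]
            new_j = pool[only_i.size:]
            m[i, only_i] = False
            m[j, only_j] = False
            m[i, new_i] = True
            m[j, new_j] = True
        occ = np.zeros(n_sp, dtype=np.int64)
        for g in range(G):
            occ += m[:, group_of_sample == g].any(axis=1)
        counts[b] = np.bincount(occ, minlength=G + 1)[1:G + 1]
    return counts, counts.mean(axis=0)


def occupancy_null(table: pd.DataFrame, meta: pd.DataFrame,
                   n_perm: int = 100000, seed=None, min_count: int = 1,
                   null: str = "redraw") -> OccupancyResult:
    """Observed vs permutation-expected occupancy histogram.

    The default "redraw" null redraws each species' incidence set uniformly
    among all samples, holding its number of occupied samples fixed.  The
    "fixedfixed" null additionally preserves per-sample richness (curveball
    trades); it is markedly slower and intended for sensitivity checks at
    smaller ``n_perm``.  Upper-tail per-class p-values carry the (b+1)/(B+1)
    correction; exceedance is the strict inequality observed > expected.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    table, meta = _align(table, meta)
    occ = compute_occupancy(table, meta, min_count=min_count)
    pres = (table.loc[occ.index] >= min_count).to_numpy()
    group_labels = meta["group"].unique()
    gidx = {g: i for i, g in enumerate(group_labels)}
    group_of_sample = np.array([gidx[g] for g in
                                meta.set_index("sample_id").loc[
                                    list(table.columns), "group"]])
    group_sizes = np.bincount(group_of_sample)
    G = len(group_sizes)
    classes = np.arange(1, G + 1)
    observed = np.bincount(occ.to_numpy(), minlength=G + 1)[1:G + 1]
    rng = np.random.default_rng(seed)
    k_per_species = pres.sum(axis=1)
    if null == "redraw":
        counts, expected = _null_redraw(k_per_species, group_sizes,
                                        n_perm, rng)
    elif null == "fixedfixed":
        counts, expected = _null_fixedfixed(pres, group_of_sample,
                                            n_perm, rng)
    else:
        raise ValueError("null must be 'redraw' or 'fixedfixed'")
    pvals = ((counts >= observed[None, :]).sum(axis=0) + 1) / (n_perm + 1)
    exceed = observed > expected
    return OccupancyResult(occupancy=occ, classes=classes,
                           observed_hist=observed, expected_hist=expected,
                           exceedance=exceed, pvalues=pvals,
                           n_perm=n_perm, null=null)


def classify_species(occ: OccupancyResult) -> ClassificationResult:
    """Label species sensitive / resistant / other from exceedance runs.

    Sensitive: occupancy in the maximal run of exceedance classes starting at
    occupancy 1.  Resistant: occupancy in the maximal run ending at G.  A
    missing run leaves the corresponding label set empty (with a warning).
    """
    G = len(occ.classes)
    ex = occ.exceedance
    sens = []
    for c in range(G):
        if ex[c]:
            sens.append(c + 1)
        else:
            break
    resist = []
    for c in range(G - 1, -1, -1):
        if ex[c]:
            resist.append(c + 1)
        else:
            break
    resist = resist[::-1]
    if sens and resist and sens[-1] >= resist[0]:
        warnings.warn("exceedance covers every occupancy class; "
                      "classification is degenerate, labelling all 'other'",
                      UserWarning)
        sens, resist = [], []
    if not sens:
        warnings.warn("no exceedance at occupancy 1: sensitive set empty",
                      UserWarning)
    if not resist:
        warnings.warn(f"no exceedance at occupancy {G}: resistant set empty",
                      UserWarning)
    labels = pd.Series("other", index=occ.occupancy.index, name="label")
    if sens:
        labels[occ.occupancy.isin(sens)] = "sensitive"
    if resist:
        labels[occ.occupancy.isin(resist)] = "resistant"
    return ClassificationResult(labels=labels,
                                sensitive_classes=tuple(sens),
                                resistant_classes=tuple(resist))


class OccupancyClassifier(BaseEstimator):
    """Permutation-null occupancy classifier (scikit-learn style).

    ``fit(table, meta)`` computes occupancy, the permutation null and the
    sensitive/resistant/other labels.

    Attributes
    ----------
    occupancy_ : Series
    result_ : OccupancyResult
    labels_ : Series
    sensitive_classes_, resistant_classes_ : tuple of int
    """

    def __init__(self, n_perm: int = 100000, min_count: int = 1,
                 null: str = "redraw", random_state=None):
        self.n_perm = n_perm
        self.min_count = min_count
        self.null = null
        self.random_state = random_state

    def fit(self, table, meta):
        self.result_ = occupancy_null(table, meta, n_perm=self.n_perm,
                                      seed=self.random_state,
                                      min_count=self.min_count,
                                      null=self.null)
        self.occupancy_ = self.result_.occupancy
        cls = classify_species(self.result_)
        self.classification_ = cls
        self.labels_ = cls.labels
        self.sensitive_classes_ = cls.sensitive_classes
        self.resistant_classes_ = cls.resistant_classes
        return self
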