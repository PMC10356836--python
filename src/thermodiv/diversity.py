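"""Alpha diversity, community phylogenetics and trait-signal statistics.

Covers per-sample taxonomic diversity (richness, inverse Simpson, Shannon),
mean nearest-taxon distance (MNTD) with its randomization-null standardized
form (NTI), Levins' niche breadth over temperature groups, abundance-weighted
environmental-preference traits, and Blomberg's K phylogenetic signal.

Sign convention: NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null), so
phylogenetic clustering (observed MNTD below the null mean) gives positive
NTI.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import trees as _trees

__all__ = [
    "alpha_diversity",
    "mntd",
    "nti",
    "levins_breadth",
    "species_breadths",
    "community_mean_breadth",
    "env_preference_trait",
    "blomberg_k",
    "diversity_profile",
    "vcv_matrix",
    "pic_contrasts",
]


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, inverse Simpson, classical Simpson and Shannon.

    All-zero samples yield NaN and a warning.
    """
    out = []
    for s in table.columns:
        x = table[s].to_numpy(dtype=float)
        tot = x.sum()
        if tot <= 0:
            warnings.warn(f"sample {s} has no counts; diversity undefined",
                          UserWarning)
            out.append({"sample_id": s, "richness": np.nan,
                        "inverse_simpson": np.nan, "simpson": np.nan,
                        "shannon": np.nan})
            continue
        p = x[x > 0] / tot
        out.append({
            "sample_id": s,
            "richness": int((x > 0).sum()),
            "inverse_simpson": 1.0 / np.sum(p ** 2),
            "simpson": 1.0 - np.sum(p ** 2),
            "shannon": float(-np.sum(p * np.log(p))),
        })
    return pd.DataFrame(out).set_index("sample_id")


def _as_pdm(tree_or_pdm):
    if isinstance(tree_or_pdm, tuple):
        labels, D = tree_or_pdm
        return list(labels), np.asarray(D)
    return _trees.patristic_matrix(tree_or_pdm)


def mntd(tree_or_pdm, taxa, abundances=None) -> float:
    """Mean distance from each sample taxon to its nearest co-occurring taxon.

    ``tree_or_pdm`` is a dendropy tree or a cached ``(labels, D)`` patristic
    matrix (cache it when calling repeatedly — the null loop must not
    recompute distances).  With ``abundances`` the per-taxon nearest-neighbor
    distances are weighted by relative abundance.
    """
    labels, D = _as_pdm(tree_or_pdm)
    pos = {l: i for i, l in enumerate(labels)}
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("MNTD needs >= 2 taxa present on the tree")
    idx = np.array([pos[t] for t in taxa])
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if abundances is None:
        return float(nearest.mean())
    w = np.asarray([abundances[t] for t in taxa], dtype=float)
    w = w / w.sum()
    return float(np.sum(w * nearest))


def nti(tree_or_pdm, taxa, n_null: int = 999, seed=None,
        abundances=None):
    """Nearest-taxon index against a tip-shuffling null.

    The null shuffles tip labels across the whole pool tree (equivalently:
    draws random tip sets of the same richness) ``n_null`` times and
    standardizes the observed MNTD: NTI = -(obs - mean) / sd.  A degenerate
    null (sd = 0, e.g. the sample is the entire pool) reports NTI = 0 with
    ``degenerate=True``.

    Returns (nti, degenerate_flag).
    """
    labels, D = _as_pdm(tree_or_pdm)
    obs = mntd((labels, D), taxa, abundances=abundances)
    rng = np.random.default_rng(seed)
    n = len(labels)
    k = len(list(taxa))
    sub_ab = None
    if abundances is not None:
        sub_ab = np.asarray([abundances[t] for t in taxa], dtype=float)
    nulls = np.empty(n_null)
    for b in range(n_null):
        idx = rng.choice(n, size=k, replace=False)
        sub = D[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        nearest = sub.min(axis=1)
        if sub_ab is None:
            nulls[b] = nearest.mean()
        else:
            w = sub_ab / sub_ab.sum()
            nulls[b] = np.sum(w * nearest)
    sd = nulls.std(ddof=1)
    mean = nulls.mean()
    # summation-order noise can leave a ~1e-16 spread in a degenerate null
    if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, abs(mean)):
        return 0.0, True
    return float(-(obs - mean) / sd), False


def levins_breadth(group_abundance) -> float:
    """Levins' niche breadth B = 1 / sum(p_h^2) over resource states."""
    x = np.asarray(group_abundance, dtype=float)
    tot = x.sum()
    if tot <= 0:
        raise ValueError("species has zero total abundance")
    p = x / tot
    return float(1.0 / np.sum(p ** 2))


def _group_abundance(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    groups = meta.set_index("sample_id")["group"]
    return table.T.groupby(groups).sum().T


def species_breadths(table: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Levins breadth per species over temperature groups."""
    ga = _group_abundance(table, meta)
    ga = ga.loc[ga.sum(axis=1) > 0]
    p = ga.div(ga.sum(axis=1), axis=0)
    b = 1.0 / (p ** 2).sum(axis=1)
    b.name = "levins_breadth"
    return b


def community_mean_breadth(table: pd.DataFrame, meta: pd.DataFrame,
                           labels=None, label=None,
                           per: str = "sample") -> pd.Series:
    """Mean Levins breadth of the species present, per sample or per class.

    ``labels``/``label`` optionally restrict to one classification label.
    """
    b = species_breadths(table, meta)
    if labels is not None and label is not None:
        keep = [sp for sp in b.index if labels.get(sp) == label]
        b = b.loc[keep]
    if per == "species":
        return b
    out = {}
    for s in table.columns:
        present = table.index[(table[s] > 0)].intersection(b.index)
        out[s] = float(b.loc[present].mean()) if len(present) else np.nan
    return pd.Series(out, name="mean_levins_breadth")


def env_preference_trait(table: pd.DataFrame, meta: pd.DataFrame,
                         variable: str = "temperature_C") -> pd.Series:
    """Abundance-weighted mean of an environmental variable per species."""
    if variable not in meta.columns:
        raise KeyError(f"{variable!r} not in metadata")
    x = meta.set_index("sample_id")[variable].loc[list(table.columns)]
    tot = table.sum(axis=1)
    keep = tot > 0
    trait = (table.loc[keep] * x.to_numpy()[None, :]).sum(axis=1) / tot[keep]
    trait.name = variable
    return trait


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

def vcv_matrix(tree):
    """Brownian-motion covariance implied by the tree: shared root-to-MRCA
    path length between tips (polytomies allowed).  Returns (labels, C)."""
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    labels = [lf.taxon.label if lf.taxon else f"tip{i}"
              for i, lf in enumerate(leaves)]
    pos = {id(lf): i for i, lf in enumerate(leaves)}
    rootdist = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            rootdist[id(nd)] = 0.0
        else:
            rootdist[id(nd)] = rootdist[id(nd.parent_node)] \
                + (nd.edge.length or 0.0)
    C = np.zeros((n, n))
    below = {}
    for lf in leaves:
        below[id(lf)] = np.array([pos[id(lf)]])
        C[pos[id(lf)], pos[id(lf)]] = rootdist[id(lf)]
    for nd in tree.postorder_internal_node_iter():
        parts = [below.pop(id(ch)) for ch in nd.child_nodes()]
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                C[np.ix_(parts[i], parts[j])] = rootdist[id(nd)]
                C[np.ix_(parts[j], parts[i])] = rootdist[id(nd)]
        below[id(nd)] = np.concatenate(parts)
    return labels, C


def pic_contrasts(tree, trait: dict) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts."""
    arr = _trees.to_arrays(tree)
    x = np.empty(arr.n_nodes)
    v = arr.blen.astype(float).copy()
    for i, lab in enumerate(arr.tip_labels):
        x[i] = trait[lab]
    contrasts = np.empty(arr.n_tips - 1)
    for j in range(arr.n_tips - 1):
        node = arr.n_tips + j
        l, r = arr.left[j], arr.right[j]
        vl, vr = v[l], v[r]
        contrasts[j] = (x[l] - x[r]) / np.sqrt(vl + vr)
        x[node] = (x[l] / vl + x[r] / vr) / (1.0 / vl + 1.0 / vr) \
            if vl > 0 and vr > 0 else 0.5 * (x[l] + x[r])
        v[node] += (vl * vr) / (vl + vr) if (vl + vr) > 0 else 0.0
    return contrasts


def blomberg_k(tree, trait, n_perm: int = 999, seed=None):
    """Blomberg's K and a tip-permutation p-value.

    K compares the observed ratio MSE0/MSE (variance about the
    phylogenetically weighted mean over the GLS error) to its Brownian-motion
    expectation; K = 1 is the Brownian benchmark, K > 1 stronger signal.  The
    p-value compares the observed variance of the independent contrasts to
    tip-shuffled permutations (lower observed variance = stronger signal).

    Returns (K, p).  A constant trait returns K = 0 with p = 1.
    """
    if hasattr(trait, "to_dict"):
        trait = trait.to_dict()
    labels, C = vcv_matrix(tree)
    missing = [l for l in labels if l not in trait]
    if missing:
        raise KeyError(f"trait missing for tips {missing[:5]}")
    x = np.array([float(trait[l]) for l in labels])
    n = x.size
    if n < 4:
        raise ValueError("Blomberg's K needs >= 4 tips")
    if np.allclose(x, x[0]):
        return 0.0, 1.0
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        raise ValueError("singular phylogenetic covariance: degenerate tree")
    one = np.ones(n)
    denom_a = one @ Cinv @ one
    a_hat = (one @ Cinv @ x) / denom_a
    resid = x - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ Cinv @ resid / (n - 1)
    expected_ratio = (np.trace(C) - n / denom_a) / (n - 1)
    K = (mse0 / mse) / expected_ratio

    rng = np.random.default_rng(seed)
    tr = {l: v for l, v in zip(labels, x)}
    obs_var = float(np.var(pic_contrasts(tree, tr), ddof=0))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        tr = {l: v for l, v in zip(labels, perm)}
        pv = float(np.var(pic_contrasts(tree, tr), ddof=0))
        if pv <= obs_var:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(K), float(p)


def diversity_profile(table: pd.DataFrame, meta: pd.DataFrame, tree=None,
                      n_null: int = 999, seed=None,
                      abundance_weighted: bool = False) -> pd.DataFrame:
    """Per-sample diversity profile (richness, Simpson forms, Shannon, MNTD,
    NTI, mean Levins breadth).

    Phylogenetic metrics use the species resolvable to tree tips; unmatched
    species are reported once and excluded.  The patristic matrix is computed
    once and reused across samples and null draws.
    """
    prof = alpha_diversity(table)
    prof["mean_levins_breadth"] = community_mean_breadth(table, meta)
    if tree is None:
        prof["mntd"] = np.nan
        prof["nti"] = np.nan
        return prof
    labels, D = _trees.patristic_matrix(tree)
    tipset = set(labels)
    unmatched = [sp for sp in table.index if sp not in tipset]
    if unmatched:
        warnings.warn(f"{len(unmatched)} species not on the tree excluded "
                      f"from phylogenetic metrics (e.g. {unmatched[:5]})",
                      UserWarning)
    ss = np.random.SeedSequence(seed).spawn(len(table.columns))
    mntd_col, nti_col = [], []
    for s, sub_ss in zip(table.columns, ss):
        taxa = [sp for sp in table.index[table[s] > 0] if sp in tipset]
        if len(taxa) < 2:
            mntd_col.append(np.nan)
            nti_col.append(np.nan)
            continue
        ab = table[s] if abundance_weighted else None
        mntd_col.append(mntd((labels, D), taxa, abundances=ab))
        val, _deg = nti((labels, D), taxa, n_null=n_null,
                        seed=int(sub_ss.generate_state(1)[0] % (2 ** 31)),
                        abundances=ab)
        nti_col.append(val)
    prof["mntd"] = mntd_col
    prof["nti"] = nti_col
    return prof
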