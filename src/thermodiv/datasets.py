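"""Synthetic data generators for every pipeline input.

The generators emulate the study design the package targets: eight
temperature groups along a cooling hot-spring outflow (80 down to 54.8 deg C)
with seven replicate sediment samples each, a heavy-tailed (lognormal)
species-abundance distribution, planted occupancy structure (thermal-niche
specialists detected in exactly one group, generalists in at least five of
eight), and phylogenies with binary tip states simulated forward under known
binary-state speciation–extinction rates.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .bisse import RateParams
from .mte import BOLTZMANN_EV

__all__ = [
    "SimBisseConfig",
    "SimCommunityConfig",
    "simulate_bisse_tree",
    "generate_community",
    "generate_arrhenius_series",
    "make_sloan_community",
    "DEFAULT_GROUP_TEMPS",
]

# Endpoints (80, 54.8) and the printed interior anchors; the remaining values
# interpolate the outflow profile and are configurable.
DEFAULT_GROUP_TEMPS = (80.0, 75.5, 72.1, 68.0, 63.9, 60.1, 57.2, 54.8)


@dataclass
class SimBisseConfig:
    """Forward-simulation settings for one BiSSE tree."""

    rates: RateParams
    n_tips_target: int | None = None
    root_state: int = 0
    max_time: float | None = None
    seed: int | None = None
    max_retries: int = 100

    def __post_init__(self):
        if self.n_tips_target is None and self.max_time is None:
            raise ValueError("need n_tips_target or max_time")
        if self.n_tips_target is not None and self.n_tips_target < 3:
            raise ValueError("n_tips_target must be >= 3")
        if self.root_state not in (0, 1):
            raise ValueError("root_state must be 0 or 1")


def _simulate_once(rates: RateParams, root_state, n_target, max_time, rng):
    """One Gillespie draw; returns (present, birth, end, children, state,
    extant) or None if extinct / target missed."""
    lam = (rates.lambda0, rates.lambda1)
    mu = (rates.mu0, rates.mu1)
    q = (rates.q01, rates.q10)
    per = (lam[0] + mu[0] + q[0], lam[1] + mu[1] + q[1])
    birth = [0.0]
    end = [np.inf]
    children = [None]
    state = [root_state]
    active = [[], []]
    active[root_state].append(0)
    t = 0.0
    horizon = np.inf if max_time is None else max_time
    while True:
        n0, n1 = len(active[0]), len(active[1])
        n_ext = n0 + n1
        if n_ext == 0:
            return None  # total extinction
        rtot = n0 * per[0] + n1 * per[1]
        if n_target is not None and n_ext >= n_target:
            # target reached: stop just before the next event would fire, so
            # the youngest tips get a positive pendant branch
            if rtot > 0.0:
                t = t + rng.exponential(1.0 / rtot)
            present = min(t, horizon) if max_time is not None else t
            break
        if rtot <= 0.0:
            t = horizon
        else:
            t = t + rng.exponential(1.0 / rtot)
        if t >= horizon:
            if n_target is not None:
                return None  # ran out of time before reaching the target
            present = horizon
            break
        # choose state class, then a uniform member of it
        s = 0 if rng.random() * rtot < n0 * per[0] else 1
        pool = active[s]
        idx = rng.integers(len(pool))
        lin = pool[idx]
        u = rng.random() * per[s]
        if u < lam[s]:  # speciation
            pool[idx] = pool[-1]
            pool.pop()
            end[lin] = t
            for _ in range(2):
                birth.append(t)
                end.append(np.inf)
                children.append(None)
                state.append(s)
                active[s].append(len(birth) - 1)
            children[lin] = (len(birth) - 2, len(birth) - 1)
        elif u < lam[s] + mu[s]:  # extinction
            pool[idx] = pool[-1]
            pool.pop()
            end[lin] = t
        else:  # state flip
            pool[idx] = pool[-1]
            pool.pop()
            state[lin] = 1 - s
            active[1 - s].append(lin)
    extant = set(active[0]) | set(active[1])
    if len(extant) < 2:
        return None
    return present, birth, end, children, state, extant


def _build_tree(present, birth, children, state, extant):
    """Prune extinct lineages and assemble the reconstructed dendropy tree."""
    n = len(birth)
    surv = [False] * n
    for i in range(n - 1, -1, -1):
        if i in extant:
            surv[i] = True
        elif children[i] is not None:
            a, b = children[i]
            surv[i] = surv[a] or surv[b]
    taxon_ns = dendropy.TaxonNamespace()
    result = [None] * n  # (dendropy node, pendant length)
    tip_states = {}
    k = 0
    for i in range(n - 1, -1, -1):
        if not surv[i]:
            continue
        if i in extant:
            k += 1
            label = f"t{k}"
            nd = dendropy.Node()
            nd.taxon = taxon_ns.new_taxon(label)
            tip_states[label] = state[i]
            result[i] = (nd, present - birth[i])
        else:
            a, b = children[i]
            kids = [c for c in (a, b) if surv[c]]
            dur = (min(present, birth[a]) - birth[i])  # lineage duration
            if len(kids) == 2:
                nd = dendropy.Node()
                for c in kids:
                    cnd, clen = result[c]
                    cnd.edge.length = clen
                    nd.add_child(cnd)
                result[i] = (nd, dur)
            else:
                cnd, clen = result[kids[0]]
                result[i] = (cnd, clen + dur)
    root, _ = result[0]
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree, tip_states


def simulate_bisse_tree(config: SimBisseConfig):
    """Forward-simulate a BiSSE tree and return (tree, tip_states).

    Exact Gillespie event sampling; the reconstructed tree contains extant
    tips only, is rooted, binary and ultrametric, with each tip labelled by
    its state at the present.  When ``n_tips_target`` is set the simulation
    conditions on reaching at least that many extant tips and truncates at
    the moment the target is first reached; draws that go extinct or miss the
    target are rejected and re-drawn within ``max_retries``.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(config.max_retries):
        out = _simulate_once(config.rates, config.root_state,
                             config.n_tips_target, config.max_time, rng)
        if out is None:
            continue
        present, birth, end, children, state, extant = out
        tree, tip_states = _build_tree(present, birth, children, state, extant)
        if len(tip_states) < 3:
            continue
        return tree, tip_states
    raise RuntimeError(
        f"no surviving tree with the requested size in {config.max_retries} "
        "attempts: rates incompatible with n_tips_target/max_time")


# ---------------------------------------------------------------------------
# community tables with planted occupancy structure
# ---------------------------------------------------------------------------

@dataclass
class SimCommunityConfig:
    """Settings for a planted specialist/generalist community table.

    Specialists are detectable only within their home temperature group and,
    mirroring the rare majority of real surveys, occupy few replicate samples
    there (``specialist_sample_weights`` over 1..3 of 7 by default).
    Generalists cover between ``generalist_min_occupancy`` and ``n_groups``
    groups (profile skewed toward the minimum) with
    ``generalist_samples_per_group`` samples in each covered group.
    """

    n_groups: int = 8
    n_reps_per_group: int = 7
    group_temps_C: tuple = DEFAULT_GROUP_TEMPS
    n_specialists_per_group: int = 40
    n_generalists: int = 60
    generalist_min_occupancy: int = 5
    abundance_model: dict = field(
        default_factory=lambda: {"meanlog": 0.0, "sdlog": 1.0})
    sequencing_depth: int = 20000
    detection_noise: float = 0.0
    seed: int | None = None
    specialist_sample_weights: dict = field(
        default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.3})
    generalist_occupancy_weights: tuple = (0.40, 0.25, 0.20, 0.15)
    generalist_samples_per_group: int = 1

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if not (1 <= self.generalist_min_occupancy <= self.n_groups):
            raise ValueError("generalist_min_occupancy must be in 1..n_groups")
        if len(set(self.group_temps_C)) != len(self.group_temps_C):
            raise ValueError("group temperatures must be distinct")
        if len(self.group_temps_C) != self.n_groups:
            raise ValueError("group_temps_C length must equal n_groups")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")
        if not (0.0 <= self.detection_noise < 1.0):
            raise ValueError("detection_noise must be in [0, 1)")


def _largest_remainder(weights, total):
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def generate_community(config: SimCommunityConfig,
                       specialist_ids=None, generalist_ids=None):
    """Generate (AbundanceTable, SampleMetadata, TruthLabels).

    Returns
    -------
    table : DataFrame (species x samples, integer counts)
    meta : DataFrame with sample_id, group, temperature_C, replicate
    truth : DataFrame with the planted class, home group, planted occupancy
        and planted sample incidence per species (the generator's draw log).
    """
    rng = np.random.default_rng(config.seed)
    G, R = config.n_groups, config.n_reps_per_group
    groups = [f"G{g + 1}" for g in range(G)]
    samples = [f"G{g + 1}R{r + 1}" for g in range(G) for r in range(R)]
    sample_group = {s: s.split("R")[0] for s in samples}
    meta = pd.DataFrame({
        "sample_id": samples,
        "group": [sample_group[s] for s in samples],
        "temperature_C": [config.group_temps_C[int(s[1:].split("R")[0]) - 1]
                          for s in samples],
        "replicate": [int(s.split("R")[1]) for s in samples],
    })

    if specialist_ids is None:
        specialist_ids = [f"SP{g + 1}_{i + 1}"
                          for g in range(G)
                          for i in range(config.n_specialists_per_group)]
        home = [groups[g] for g in range(G)
                for _ in range(config.n_specialists_per_group)]
    else:
        specialist_ids = list(specialist_ids)
        home = [groups[i % G] for i in range(len(specialist_ids))]
    if generalist_ids is None:
        generalist_ids = [f"GEN{i + 1}" for i in range(config.n_generalists)]
    else:
        generalist_ids = list(generalist_ids)

    incidence = {}  # species -> set of samples the species can occur in
    truth_rows = []

    kw = config.specialist_sample_weights
    ks = np.array(sorted(kw))
    kp = np.array([kw[k] for k in ks], dtype=float)
    kp /= kp.sum()
    for sp, hg in zip(specialist_ids, home):
        k = int(rng.choice(ks, p=kp))
        k = min(k, R)
        reps = rng.choice(R, size=k, replace=False)
        occ = {f"{hg}R{r + 1}" for r in reps}
        incidence[sp] = occ
        truth_rows.append({"species": sp, "planted_class": "specialist",
                           "home_group": hg, "planted_occupancy": 1,
                           "planted_groups": hg,
                           "planted_n_samples": len(occ)})

    n_gen = len(generalist_ids)
    if n_gen:
        levels = list(range(config.generalist_min_occupancy, G + 1))
        w = list(config.generalist_occupancy_weights)
        if len(w) != len(levels):
            w = [1.0] * len(levels)
        counts = _largest_remainder(w, n_gen)
        occ_levels = np.repeat(levels, counts)
        occ_levels = rng.permutation(occ_levels)
        spg = config.generalist_samples_per_group
        for sp, g_occ in zip(generalist_ids, occ_levels):
            gidx = rng.choice(G, size=int(g_occ), replace=False)
            occ = set()
            for g in gidx:
                reps = rng.choice(R, size=min(spg, R), replace=False)
                occ |= {f"{groups[g]}R{r + 1}" for r in reps}
            incidence[sp] = occ
            truth_rows.append({
                "species": sp, "planted_class": "generalist",
                "home_group": "", "planted_occupancy": int(g_occ),
                "planted_groups": ",".join(groups[g] for g in sorted(gidx)),
                "planted_n_samples": len(occ)})

    species = specialist_ids + generalist_ids
    sizes = pd.Series(
        rng.lognormal(config.abundance_model.get("meanlog", 0.0),
                      config.abundance_model.get("sdlog", 1.0),
                      size=len(species)), index=species)

    # per-sample dropout applied to the planted incidence
    if config.detection_noise > 0:
        for sp in species:
            keep = {s for s in incidence[sp]
                    if rng.random() >= config.detection_noise}
            incidence[sp] = keep

    sp_index = {sp: i for i, sp in enumerate(species)}
    counts = np.zeros((len(species), len(samples)), dtype=np.int64)
    undetectable = []
    for sj, sample in enumerate(samples):
        present = [sp for sp in species if sample in incidence[sp]]
        if not present:
            continue
        w = sizes[present].to_numpy()
        p = w / w.sum()
        expected = p * config.sequencing_depth
        for sp, e in zip(present, expected):
            if e < 3.0:
                undetectable.append((sp, sample))
        draw = rng.multinomial(config.sequencing_depth, p)
        rows = [sp_index[sp] for sp in present]
        counts[rows, sj] = draw
    if undetectable:
        names = sorted({sp for sp, _ in undetectable})
        warnings.warn(
            f"sequencing_depth may be too small to detect {len(names)} "
            f"planted species reliably (e.g. {names[:5]})", UserWarning)

    table = pd.DataFrame(counts, index=pd.Index(species, name="species"),
                         columns=samples)
    truth = pd.DataFrame(truth_rows).set_index("species")
    return table, meta, truth


def generate_arrhenius_series(E_eV: float, lnA: float, temps_C,
                              noise_sd: float = 0.0, seed=None) -> np.ndarray:
    """Index values v(T) = exp(lnA - E/(k T_K)) with lognormal noise."""
    temps_C = np.asarray(temps_C, dtype=float)
    if temps_C.size == 0:
        raise ValueError("temps_C must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    T_K = temps_C + 273.15
    v = np.exp(lnA - E_eV / (BOLTZMANN_EV * T_K))
    if noise_sd > 0:
        v = v * np.exp(rng.normal(0.0, noise_sd, size=v.shape))
    return v


def make_sloan_community(n_species: int = 2000, n_samples: int = 56,
                         community_size: int = 20000, m: float = 0.05,
                         sdlog: float = 1.5, seed=None):
    """Counts drawn from the Sloan neutral model itself.

    Mean relative abundances are lognormal (normalized to 1); each sample's
    relative abundance of species i is Beta(N m p_i, N m (1 - p_i)); counts
    are floor(x N) so detection (count >= 1) coincides exactly with the
    model's detection limit d = 1/N.

    Returns (table, p_true).
    """
    rng = np.random.default_rng(seed)
    N = community_size
    p = rng.lognormal(0.0, sdlog, size=n_species)
    p /= p.sum()
    a = N * m * p
    b = N * m * (1.0 - p)
    x = rng.beta(a[:, None], b[:, None], size=(n_species, n_samples))
    counts = np.floor(x * N).astype(np.int64)
    table = pd.DataFrame(
        counts, index=pd.Index([f"S{i + 1}" for i in range(n_species)],
                               name="species"),
        columns=[f"smp{j + 1}" for j in range(n_samples)])
    return table, pd.Series(p, index=table.index, name="p_true")
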