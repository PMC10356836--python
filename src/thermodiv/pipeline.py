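"""End-to-end orchestration: occupancy classification, diversity, neutral
model, per-group BiSSE fits and MTE scaling, with reproducible seeding.

Every random stage consumes an independent sub-seed spawned from the master
seed, so toggling one stage never changes another's results, and rerunning
the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, diversity, io, mte, trees as _trees
from .bisse import RateParams, per_group_bisse
from .neutral import fit_ncm
from .occupancy import OccupancyClassifier

__all__ = ["default_synthetic_config", "run_all", "validate_inputs",
           "validate_summary"]

STAGES = ("inputs", "validate", "classify", "diversity", "ncm", "bisse",
          "mte")


def default_synthetic_config(seed: int = 0) -> dict:
    """A one-command synthetic demonstration configuration."""
    return {
        "seed": seed,
        "synthetic": {
            "tree": {
                "rates": {"lambda0": 0.15, "lambda1": 0.15,
                          "mu0": 0.02, "mu1": 0.05,
                          "q01": 0.03, "q10": 0.03},
                "n_tips_target": 260,
                "root_state": 0,
            },
            "community": {
                "sequencing_depth": 20000,
                "abundance_model": {"meanlog": 0.0, "sdlog": 1.0},
            },
        },
        "classify": {"n_perm": 20000, "min_count": 1, "null": "redraw"},
        "diversity": {"n_null": 199},
        "bisse": {"min_tips": 10, "n_restarts": 2, "root_mode": "obs",
                  "condition_survival": True},
        "mte": {"orientation": "in"},
    }


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def _sub_seed(ss) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def validate_inputs(table: pd.DataFrame, meta: pd.DataFrame,
                    tree=None) -> dict:
    """Cross-check table, metadata and tree; returns a dict of issue lists.

    An empty dict of issues means the inputs are mutually consistent.
    """
    issues = {}
    tbl_samples = set(table.columns)
    meta_samples = set(meta["sample_id"].astype(str).str.strip())
    only_tbl = sorted(tbl_samples - meta_samples)
    only_meta = sorted(meta_samples - tbl_samples)
    if only_tbl:
        issues["samples_without_metadata"] = only_tbl
    if only_meta:
        issues["metadata_samples_absent_from_table"] = only_meta
    zero = [s for s in table.columns if table[s].sum() == 0]
    if zero:
        issues["all_zero_samples"] = zero
    if tree is not None:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        unmatched = sorted(set(table.index) - tips)
        if unmatched:
            issues["species_not_on_tree"] = unmatched
        nonbinary = sum(1 for nd in tree.preorder_node_iter()
                        if len(nd.child_nodes()) > 2)
        if nonbinary:
            issues["polytomies"] = [nonbinary]
        neg = [nd.edge.length for nd in tree.preorder_node_iter()
               if nd.edge.length is not None and nd.edge.length < 0]
        if neg:
            issues["negative_branch_lengths"] = neg[:5]
        if not _trees.is_ultrametric(tree, rel_tol=0.01):
            issues["ultrametricity_deviation_over_1pct"] = [True]
    return issues


def _synthesize(cfg: dict, rng_ss) -> tuple:
    tcfg = cfg["tree"]
    rates = RateParams(**tcfg["rates"])
    ss_tree, ss_comm = rng_ss.spawn(2)
    tree, tip_states = datasets.simulate_bisse_tree(datasets.SimBisseConfig(
        rates=rates, n_tips_target=tcfg.get("n_tips_target", 260),
        root_state=tcfg.get("root_state", 0), seed=_sub_seed(ss_tree)))
    specialists = [t for t, s in tip_states.items() if s == 0]
    generalists = [t for t, s in tip_states.items() if s == 1]
    ccfg = dict(cfg.get("community", {}))
    ccfg.setdefault("seed", _sub_seed(ss_comm))
    comm_config = datasets.SimCommunityConfig(**ccfg)
    table, meta, truth = datasets.generate_community(
        comm_config, specialist_ids=specialists, generalist_ids=generalists)
    return table, meta, tree, truth


def run_all(config: dict, out_dir) -> dict:
    """Run the full analysis; writes stage outputs + summary under out_dir.

    Stage order: inputs -> validation -> occupancy classification ->
    diversity -> neutral model (whole community and per class) -> per-group
    BiSSE -> MTE indices.  Partial failures keep completed stages and record
    the reason.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.get("seed", 0))
    ss = dict(zip(STAGES, np.random.SeedSequence(master).spawn(len(STAGES))))
    seeds = {k: _sub_seed(v) for k, v in ss.items()}
    report = {"config": config, "seeds": seeds, "stages": {}}
    truth = None

    # ---- inputs
    if "synthetic" in config:
        table, meta, tree, truth = _synthesize(config["synthetic"],
                                               ss["inputs"])
        io.write_abundance_table(table, out / "abundance.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_tree(tree, out / "tree.nwk")
        truth.to_csv(out / "truth_labels.tsv", sep="\t")
    else:
        paths = config["inputs"]
        table = io.read_abundance_table(paths["table"])
        meta = io.read_metadata(paths["metadata"])
        tree = io.read_tree(paths["tree"]) if paths.get("tree") else None
    report["stages"]["inputs"] = {"status": "ok"}

    # ---- validation
    issues = validate_inputs(table, meta, tree)
    report["validation"] = issues
    if ("samples_without_metadata" in issues
            or "metadata_samples_absent_from_table" in issues):
        raise ValueError(f"sample id mismatch between table and metadata: "
                         f"{issues}")
    report["stages"]["validate"] = {"status": "ok"}

    # ---- occupancy classification
    ccfg = config.get("classify", {})
    clf = OccupancyClassifier(n_perm=ccfg.get("n_perm", 100000),
                              min_count=ccfg.get("min_count", 1),
                              null=ccfg.get("null", "redraw"),
                              random_state=_sub_seed(ss["classify"]))
    clf.fit(table, meta)
    res = clf.result_
    hist = pd.DataFrame({
        "occupancy_class": res.classes,
        "observed": res.observed_hist,
        "expected": res.expected_hist,
        "exceedance": res.exceedance,
        "pvalue": res.pvalues,
    })
    hist.to_csv(out / "occupancy_histogram.tsv", sep="\t", index=False,
                float_format=io.FLOAT_FORMAT)
    lab = pd.DataFrame({"occupancy": clf.occupancy_, "label": clf.labels_})
    lab.to_csv(out / "species_labels.tsv", sep="\t")
    report["classification"] = {
        "sensitive_classes": [int(c) for c in clf.sensitive_classes_],
        "resistant_classes": [int(c) for c in clf.resistant_classes_],
        "n_sensitive": int((clf.labels_ == "sensitive").sum()),
        "n_resistant": int((clf.labels_ == "resistant").sum()),
        "n_other": int((clf.labels_ == "other").sum()),
    }
    if truth is not None:
        planted = truth["planted_class"]
        spec_ids = planted.index[planted == "specialist"].intersection(
            clf.labels_.index)
        gen_ids = planted.index[planted == "generalist"].intersection(
            clf.labels_.index)
        report["classification"]["specialist_recovery"] = float(
            (clf.labels_.loc[spec_ids] == "sensitive").mean())
        report["classification"]["generalist_recovery"] = float(
            (clf.labels_.loc[gen_ids] == "resistant").mean())
    report["stages"]["classify"] = {"status": "ok"}

    # ---- diversity
    dcfg = config.get("diversity", {})
    prof = diversity.diversity_profile(
        table, meta, tree, n_null=dcfg.get("n_null", 999),
        seed=_sub_seed(ss["diversity"]))
    prof.to_csv(out / "diversity_profile.tsv", sep="\t",
                float_format=io.FLOAT_FORMAT)
    gmeans = prof.join(meta.set_index("sample_id")["group"]).groupby(
        "group").mean(numeric_only=True)
    report["diversity"] = {
        "per_group_mean": json.loads(gmeans.to_json(orient="index"))}
    report["stages"]["diversity"] = {"status": "ok"}

    # ---- neutral model, whole community and per class
    ncm_report = {}
    subsets = {"whole": table}
    labels = clf.labels_
    subsets["sensitive"] = table.loc[labels.index[labels == "sensitive"]]
    subsets["resistant"] = table.loc[labels.index[labels == "resistant"]]
    for name, sub in subsets.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fit_ncm(sub)
            ncm_report[name] = {"m": f.m, "Nm": f.Nm, "N": f.N, "r2": f.r2,
                                "converged": f.converged}
        except ValueError as e:
            ncm_report[name] = {"skipped": str(e)}
    report["ncm"] = ncm_report
    io.dump_json(ncm_report, out / "ncm.json")
    report["stages"]["ncm"] = {"status": "ok"}

    # ---- per-group BiSSE
    bcfg = config.get("bisse", {})
    if tree is None:
        report["stages"]["bisse"] = {"status": "skipped",
                                     "reason": "no tree supplied"}
        report["stages"]["mte"] = {"status": "skipped",
                                   "reason": "no tree supplied"}
    else:
        rates_df, fits = per_group_bisse(
            tree, labels, table, meta,
            min_count=ccfg.get("min_count", 1),
            min_tips=bcfg.get("min_tips", 10),
            root_mode=bcfg.get("root_mode", "obs"),
            condition_survival=bcfg.get("condition_survival", True),
            n_restarts=bcfg.get("n_restarts", 3),
            random_state=_sub_seed(ss["bisse"]))
        rates_df.to_csv(out / "group_rates.tsv", sep="\t", index=False,
                        float_format=io.FLOAT_FORMAT)
        report["bisse"] = {
            "n_groups_fit": int((rates_df["skipped_reason"] == "").sum()),
            "n_groups_skipped": int((rates_df["skipped_reason"] != "").sum()),
        }
        report["stages"]["bisse"] = {"status": "ok"}

        # ---- MTE scaling
        mcfg = config.get("mte", {})
        series = mte.index_series(rates_df,
                                  orientation=mcfg.get("orientation", "in"))
        series.to_csv(out / "index_series.tsv", sep="\t", index=False,
                      float_format=io.FLOAT_FORMAT)
        mte_report = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for col, key in (("DP_in", "E_DP_in"), ("DP_out", "E_DP_out"),
                             ("EP", "E_EP")):
                try:
                    f = mte.arrhenius_fit(series[col].to_numpy(),
                                          series["temperature_C"].to_numpy())
                    mte_report[key] = {"E": f.E, "slope": f.slope, "r2": f.r2,
                                       "p": f.pvalue, "n": f.n_used}
                except (ValueError, KeyError) as e:
                    mte_report[key] = {"skipped": str(e)}
            try:
                _, fr = mte.relative_strength(
                    series["DP"].to_numpy(), series["EP"].to_numpy(),
                    series["temperature_C"].to_numpy())
                mte_report["E_RS"] = ({"E": fr.E, "slope": fr.slope,
                                       "r2": fr.r2, "p": fr.pvalue,
                                       "n": fr.n_used}
                                      if fr is not None else
                                      {"skipped": "no positive RS values"})
            except KeyError as e:
                mte_report["E_RS"] = {"skipped": str(e)}
        report["mte"] = mte_report
        io.dump_json(mte_report, out / "mte.json")
        report["stages"]["mte"] = {"status": "ok"}

    validate_summary(report)
    io.dump_json(report, out / "summary.json")
    (out / "run.log").write_text(
        "thermodiv run\nconfig:\n" + json.dumps(config, indent=2,
                                                sort_keys=True)
        + "\nseeds:\n" + json.dumps(seeds, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# summary schema validation (subset of JSON Schema sufficient for our file)
# ---------------------------------------------------------------------------

def _check(instance, schema, path="$"):
    t = schema.get("type")
    typemap = {"object": dict, "array": list, "string": str,
               "integer": int, "number": (int, float), "boolean": bool}
    if t is not None and not isinstance(instance, typemap[t]):
        raise ValueError(f"{path}: expected {t}, got {type(instance).__name__}")
    if "enum" in schema and instance not in schema["enum"]:
        raise ValueError(f"{path}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                raise ValueError(f"{path}: missing required key {req!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, val in instance.items():
                if key not in props:
                    _check(val, extra, f"{path}.{key}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]")


def validate_summary(summary: dict) -> None:
    """Validate a run summary against the schema shipped with the package."""
    schema = json.loads(
        importlib.resources.files("thermodiv").joinpath(
            "schema/summary.schema.json").read_text())
    _check(summary, schema)
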