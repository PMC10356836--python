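"""Reading and writing the pipeline's plain-text formats.

Tables are TSV with a single header row (species rows x sample columns for
abundance tables), trees are newick, configuration is YAML or JSON, and
summaries are JSON.  Tabular floats are written at 6 significant digits;
JSON keeps full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
import yaml

__all__ = [
    "read_abundance_table", "write_abundance_table",
    "read_metadata", "write_metadata",
    "read_tree", "write_tree",
    "read_states", "write_states",
    "load_config", "dump_json",
]

FLOAT_FORMAT = "%.6g"


def read_abundance_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate species ids: {dup}")
    return df.astype(int)


def write_abundance_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "temperature_C"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_states(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str).str.strip(),
                    df.iloc[:, 1].astype(int)))


def write_states(states: dict, path) -> None:
    pd.DataFrame({"species": list(states), "state": list(states.values())}
                 ).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
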