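"""Delimited-table and manifest I/O.

All tables are plain tab-separated text.  Tables written by the pipeline
carry a leading ``# key=value`` comment header (notably the config hash) so
any output can be traced to the exact run configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_psms(path) -> pd.DataFrame:
    df = read_table(path)
    df["modifications"] = df["modifications"].fillna("")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def write_json(payload: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
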