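"""Plain-text readers/writers for the matrix and table formats used here.

All matrices are TSV with the row-name in the first column and a header
row. Target annotations are two columns (drug, semicolon-separated
targets); combination records are four columns (drug1, drug2, cell,
synergy).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .stratification import SynergyRecord


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_target_annotation(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("target annotation needs columns: drug, targets")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        targets = {t for t in str(row.iloc[1]).split(";") if t and t != "nan"}
        out[str(row.iloc[0])] = targets
    return out


def write_target_annotation(annotation: dict[str, set[str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"drug": d, "targets": ";".join(sorted(ts))}
        for d, ts in sorted(annotation.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_combos(path) -> list[SynergyRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"drug1", "drug2", "cell", "synergy"}
    if not required.issubset(df.columns):
        raise ValueError(f"combos table needs columns {sorted(required)}")
    return [
        SynergyRecord(
            drug1=str(r.drug1), drug2=str(r.drug2), cell=str(r.cell),
            synergy=float(r.synergy),
        )
        for r in df.itertuples()
    ]


def write_combos(records: list[SynergyRecord], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"drug1": r.drug1, "drug2": r.drug2, "cell": r.cell, "synergy": r.synergy}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
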