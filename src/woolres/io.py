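"""Plain-text readers and writers for every pipeline artifact.

All tables are CSV with a fixed, documented column order and an empty field
as the missing-value sentinel; the curve store is JSON.  Every writer is
deterministic so identical inputs hash identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import Pedigree

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_records", "read_records",
    "write_genotypes", "read_genotypes",
    "write_table", "read_table",
    "write_curve_store", "read_curve_store",
]

RECORD_COLUMNS = [
    "animal", "series", "position", "value", "flock_year",
    "sex", "brt", "weaning_age", "staple_length", "sampling_age",
]


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """animal,sire,dam,generation CSV with 0 = unknown parent."""
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path: str | Path, cohort: pd.DataFrame | None = None) -> Pedigree:
    df = pd.read_csv(path)
    return Pedigree(
        df["animal"].to_numpy(), df["sire"].to_numpy(),
        df["dam"].to_numpy(), df["generation"].to_numpy(), cohort=cohort,
    )


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_genotypes(geno: np.ndarray, ids: np.ndarray, path: str | Path) -> None:
    """Whitespace-delimited dosage text: header of SNP ids, one row per
    animal starting with its id (PLINK .raw-like dialect)."""
    n_snps = geno.shape[1]
    with open(path, "w") as fh:
        fh.write("ID " + " ".join(f"SNP{j + 1}" for j in range(n_snps)) + "\n")
        for aid, row in zip(ids, geno):
            fh.write(str(int(aid)) + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_genotypes(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (ids, dosage matrix)."""
    df = pd.read_csv(path, sep=r"\s+")
    ids = df.iloc[:, 0].to_numpy(dtype=np.int64)
    return ids, df.iloc[:, 1:].to_numpy(dtype=np.int8)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_curve_store(store: dict, path: str | Path) -> None:
    """Spline coefficients per animal x series, JSON-serializable layout:
    {"<animal>:<series>": {"knots": [...], "order": k, "coefficients": [...],
    "domain": [lo, hi]}}."""

    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(store, fh, default=enc, sort_keys=True)


def read_curve_store(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
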