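"""Machine-readable reference-model and region tables with tally helpers.

hg38 fills former centromeric gaps with "reference models" — stochastic
read-derived stand-in contigs for the HOR arrays.  The bundled TSVs list
the 66 unique SF-annotated reference models (after merging models shared
between chromosomes), the pure-R2 regions and the mixed new-family/SF5
regions, as transcribed fixtures.  A checksum guards against accidental
edits; five models known to be assembled with reversed monomer order are
flagged ``misassembled``.
"""

from __future__ import annotations

import hashlib
import os
from typing import Callable

import pandas as pd

_TABLE_DIR = os.path.join(os.path.dirname(__file__), "data", "tables")

#: sha256 of the bundled fixtures; recomputed on load
TABLE_CHECKSUMS = {
    "table2_refmodels.tsv":
        "d53f401bfe3651926c7ca8201703df99d9aa36bb355b653aa68d131958271898",
    "table3_pure_r2.tsv":
        "f3bde3b865f0689539f83bf42646dbab2bb26eb962cbb2263adb73ef4d996382",
    "table4_mixed.tsv":
        "498f774fed3a16a33d5202782ce8f8812d453cf4164fb81292a67e93a06729d2",
}

SF_LABELS = {"1", "2", "3", "5", "4+", "1,5", "2,5"}


class TableIntegrityError(Exception):
    pass


def _load(name: str) -> pd.DataFrame:
    path = os.path.join(_TABLE_DIR, name)
    with open(path, "rb") as fh:
        digest = hashlib.sha256(fh.read()).hexdigest()
    expected = TABLE_CHECKSUMS[name]
    if digest != expected:
        raise TableIntegrityError(
            f"{name}: checksum {digest} != expected {expected}; "
            "the bundled fixture was modified"
        )
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def load_refmodels() -> pd.DataFrame:
    """The 66 unique AS reference models (accession, size, SF, live state)."""
    df = _load("table2_refmodels.tsv")
    df["size_bp"] = df["size_bp"].astype(int)
    bad = set(df["sf"]) - SF_LABELS
    if bad:
        raise TableIntegrityError(f"unexpected SF labels {bad}")
    if df["accession"].duplicated().any():
        raise TableIntegrityError("duplicate accession in reference model table")
    return df


def load_pure_r2() -> pd.DataFrame:
    df = _load("table3_pure_r2.tsv")
    for col in ("size_bp", "r2_pct", "bbox_pct"):
        df[col] = df[col].astype(int)
    return df


def load_mixed() -> pd.DataFrame:
    df = _load("table4_mixed.tsv")
    for col in ("size_bp", "sf1_pct", "sf2_pct", "sf5_pct"):
        df[col] = df[col].astype(int)
    return df


def tally(rows: pd.DataFrame, predicate: Callable[[pd.Series], bool]) -> int:
    """Count rows matching an arbitrary row predicate."""
    if len(rows) == 0:
        return 0
    return int(rows.apply(predicate, axis=1).sum())


def is_autosomal(chroms: str) -> bool:
    """True when none of the listed chromosomes is X or Y."""
    names = [c.strip() for c in chroms.replace("chr", "").split(",")]
    return not any(c in ("X", "Y") for c in names)


def refmodel_counts(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Standard tallies over the unique reference models."""
    df = load_refmodels() if df is None else df
    live = df["state"] == "live"
    return {
        "unique_models": len(df),
        "live_autosomal": tally(df, lambda r: r["state"] == "live" and is_autosomal(r["chroms"])),
        "live_sex": tally(df, lambda r: r["state"] == "live" and not is_autosomal(r["chroms"])),
        "nonlive_new_family": tally(
            df,
            lambda r: r["state"] != "live" and r["sf"] in ("1", "2", "3", "1,5", "2,5"),
        ),
        "nonlive_sf5": tally(df, lambda r: r["state"] != "live" and r["sf"] == "5"),
        "nonlive_sf4plus": tally(df, lambda r: r["state"] != "live" and r["sf"] == "4+"),
        "live_total": int(live.sum()),
        "misassembled": int((df["misassembled"] == "yes").sum()),
    }
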