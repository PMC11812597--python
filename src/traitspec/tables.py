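"""Readers and writers for summary-statistic tables and BED intervals.

All tables are tab-separated with a header row; BED input is 0-based
half-open and converted to the package-internal 1-based inclusive
convention on read.  Schema validation rejects malformed rows with
line-numbered messages (logged to standard error) rather than failing the
whole load; a missing required column is a hard :class:`SchemaError`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "SCHEMAS", "read_table", "write_table", "read_bed", "write_bed"]

logger = logging.getLogger("traitspec")


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


#: required columns and their kinds per table type; "pval" columns are
#: additionally range-checked to (0, 1]
SCHEMAS: dict[str, dict] = {
    "gwas": {"required": {"variant": str, "chrom": str, "pos": int, "pval": float},
             "optional": {"maf": float, "beta": float, "se": float}},
    "hits": {"required": {"variant": str, "chrom": str, "pos": int, "pval": float},
             "optional": {"maf": float, "beta": float, "se": float}},
    "burden": {"required": {"gene": str, "beta": float, "se": float, "pval": float},
               "optional": {"trait": int, "p_lof": float}},
    "genes": {"required": {"gene": str, "chrom": str, "start": int, "end": int},
              "optional": {"midpoint": int, "mu_l": float, "s_het": float}},
    "truth": {"required": {"gene": str, "chrom": str, "start": int, "end": int,
                           "s_het": float, "mu_l": float, "p_lof": float},
              "optional": {}},
}

_POSITIVE_COLS = {"pos": 1, "start": 1, "se": 0}


def read_table(path, kind: str) -> pd.DataFrame:
    """Load and validate a tab-separated summary table.

    Rows violating numeric invariants (unparseable numbers, p-values
    outside (0, 1], non-positive standard errors or positions) are dropped
    with a line-numbered log message; the rejection count is logged.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; know {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = SCHEMAS[kind]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(schema["required"]) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)} for kind {kind!r}"
        )
    bad = np.zeros(len(df), dtype=bool)
    typed = {}
    for col, typ in {**schema["required"], **schema["optional"]}.items():
        if col not in df.columns:
            continue
        if typ is str:
            typed[col] = df[col].astype(str)
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        invalid = ~np.isfinite(values)
        if col == "pval":
            invalid |= (values <= 0) | (values > 1)
        elif col in _POSITIVE_COLS:
            invalid |= ~(values >= _POSITIVE_COLS[col]) if col != "se" else ~(values > 0)
        for line in np.flatnonzero(invalid.to_numpy() & ~bad)[:20]:
            # +2: one for the header, one for 1-based line numbers
            logger.warning("%s:%d: invalid %s value %r; row rejected",
                           path, line + 2, col, df.at[line, col])
        bad |= invalid.to_numpy()
        typed[col] = values
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: rejected %d of %d rows failing schema %r",
                       path, n_bad, len(df), kind)
    out = pd.DataFrame({c: s[~bad] for c, s in typed.items()}).reset_index(drop=True)
    for col, typ in {**schema["required"], **schema["optional"]}.items():
        if col in out.columns and typ is int:
            out[col] = out[col].astype(np.int64)
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as TSV with header (the universal flat-file format here)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Load LD blocks from BED (0-based half-open) into internal coordinates.

    Returns a frame (chrom, start, end) with 1-based inclusive coordinates.
    Rows with ``start >= end`` are rejected with their line number;
    overlapping blocks within a chromosome are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if raw.shape[1] < 3:
        raise SchemaError(f"{path}: BED requires at least 3 columns")
    chrom = raw[0].astype(str)
    start = pd.to_numeric(raw[1], errors="coerce")
    end = pd.to_numeric(raw[2], errors="coerce")
    bad = ~np.isfinite(start) | ~np.isfinite(end) | (start < 0) | (start >= end)
    for line in np.flatnonzero(bad.to_numpy())[:20]:
        logger.warning("%s:%d: invalid BED interval (%r, %r); row rejected",
                       path, line + 1, raw.at[line, 1], raw.at[line, 2])
    blocks = pd.DataFrame({
        "chrom": chrom[~bad],
        "start": start[~bad].astype(np.int64) + 1,  # half-open -> 1-based inclusive
        "end": end[~bad].astype(np.int64),
    }).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for c, sub in blocks.groupby("chrom", sort=False):
        if (sub["start"].to_numpy()[1:] <= sub["end"].to_numpy()[:-1]).any():
            raise SchemaError(f"{path}: overlapping LD blocks on {c}")
    return blocks


def write_bed(blocks: pd.DataFrame, path) -> None:
    """Write blocks held in BED convention (0-based half-open) to a BED file."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    blocks[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)
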