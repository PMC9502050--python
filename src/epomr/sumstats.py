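"""GWAS summary-statistics table format.

The pipeline's universal currency is a per-variant association table with
the columns below (tab separated on disk). Coordinates are 1-based; A1 is
the effect allele; BETA is the per-A1-allele effect on the analysis scale
(phenotype SD for quantitative traits, log-odds for binary outcomes).
P-values below the underflow floor are stored at the floor with a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Mandatory columns of a summary-statistics table, in canonical order.
SUMSTATS_COLUMNS = [
    "SNP", "CHR", "POS", "A1", "A2", "FREQ_A1", "BETA", "SE", "P", "N", "INFO",
]

#: Smallest representable p-value; smaller values are floored and flagged.
P_FLOOR = 1e-320

_NUMERIC = ["POS", "FREQ_A1", "BETA", "SE", "P", "N", "INFO"]


def floor_pvalues(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip p-values at the underflow floor; return (floored, was_floored)."""
    p = np.asarray(p, dtype=float)
    flag = p < P_FLOOR
    return np.where(flag, P_FLOOR, p), flag


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory columns exist; raise SchemaError naming the first missing."""
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    return df


def _row_ok(row) -> str | None:
    """Return a rejection reason for a malformed row, or None if it is valid."""
    if not np.isfinite(row.SE) or row.SE <= 0:
        return "non-positive SE"
    if not (0 < row.P <= 1):
        return "p-value outside (0, 1]"
    if not (0 < row.FREQ_A1 < 1):
        return "allele frequency outside (0, 1)"
    if row.A1 == row.A2:
        return "identical alleles"
    if not (0 <= row.INFO <= 1.0 + 1e-9):
        return "Info outside [0, 1]"
    return None


def read_sumstats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV, dropping malformed rows.

    Alleles are uppercased. Rejected rows are logged (with their 1-based data
    line number) in the returned frame's ``.attrs["rejected"]`` list of
    ``(line_number, snp_id, reason)`` tuples.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    validate_sumstats(df)
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    rejected = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        reason = _row_ok(row)
        bad_num = any(not np.isfinite(getattr(row, c)) for c in _NUMERIC)
        if bad_num:
            reason = "non-numeric field"
        if reason is not None:
            keep[i] = False
            rejected.append((i + 2, row.SNP, reason))  # +2: header is line 1
    out = df[keep].reset_index(drop=True)
    out.attrs["rejected"] = rejected
    return out


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics table as TSV in canonical column order."""
    validate_sumstats(df)
    extra = [c for c in df.columns if c not in SUMSTATS_COLUMNS]
    df[SUMSTATS_COLUMNS + extra].to_csv(path, sep="\t", index=False)
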