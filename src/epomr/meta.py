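"""Allele alignment and fixed-effects meta-analysis of summary statistics.

Implements METAL-style inverse-variance-weighted pooling (the scheme used
for the biomarker and for pooling outcome GWAS sources) and a
sample-size-weighted z-score scheme for eQTL-style inputs where only test
statistics are comparable across studies. Heterogeneity (Cochran's Q) is
computed but never used for filtering: the analysis is fixed-effects only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import floor_pvalues

PALINDROMIC = ({"A", "T"}, {"C", "G"})

#: Drop palindromic variants whose minor-allele frequency exceeds this.
PALINDROMIC_MAF = 0.42


def _key(chrom, pos, a1, a2) -> tuple:
    return (str(chrom), int(pos)) + tuple(sorted((a1, a2)))


def align_alleles(
    stats_df: pd.DataFrame,
    reference_panel: pd.DataFrame,
    palindromic_maf: float = PALINDROMIC_MAF,
    drop_palindromic: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orient effect alleles to a reference panel.

    Variants are matched on chromosome, position and the unordered allele
    pair. Records whose alleles are swapped relative to the reference have
    BETA negated and FREQ_A1 replaced by 1 - FREQ_A1. Unmatched records are
    dropped; palindromic (A/T, C/G) variants with minor-allele frequency
    above ``palindromic_maf`` are strand-ambiguous and dropped by default.

    Returns (aligned table, drop log with snp_id + reason).
    """
    ref = {
        _key(r.CHR, r.POS, r.A1, r.A2): (r.A1, r.A2)
        for r in reference_panel.itertuples(index=False)
    }
    rows, dropped = [], []
    for r in stats_df.itertuples(index=False):
        alleles = {r.A1, r.A2}
        if drop_palindromic and alleles in PALINDROMIC:
            if min(r.FREQ_A1, 1.0 - r.FREQ_A1) > palindromic_maf:
                dropped.append((r.SNP, "palindromic, ambiguous frequency"))
                continue
        k = _key(r.CHR, r.POS, r.A1, r.A2)
        if k not in ref:
            dropped.append((r.SNP, "no reference match"))
            continue
        ref_a1, ref_a2 = ref[k]
        d = r._asdict()
        if (r.A1, r.A2) == (ref_a1, ref_a2):
            pass
        elif (r.A2, r.A1) == (ref_a1, ref_a2):
            d["A1"], d["A2"] = ref_a1, ref_a2
            d["BETA"] = -d["BETA"]
            d["FREQ_A1"] = 1.0 - d["FREQ_A1"]
        else:  # same unordered pair but inconsistent labels: cannot happen
            dropped.append((r.SNP, "allele mismatch"))
            continue
        rows.append(d)
    aligned = pd.DataFrame(rows, columns=stats_df.columns)
    log = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    return aligned.reset_index(drop=True), log


def _stack(studies: list[pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for i, df in enumerate(studies):
        d = df.copy()
        d["_study"] = i
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def ivw_meta(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    Inputs must already be allele-aligned to a common reference. Per
    variant: weights ``w = 1/SE^2``, pooled effect ``sum(w b)/sum(w)``,
    pooled SE ``1/sqrt(sum w)``, two-sided normal p, Cochran's Q, summed
    sample size, contributing-study count and per-study sign string.
    """
    cat = _stack(studies)
    cat = cat[np.isfinite(cat["SE"]) & (cat["SE"] > 0)]
    cat["_w"] = 1.0 / cat["SE"] ** 2
    cat["_wb"] = cat["_w"] * cat["BETA"]
    cat["_wf"] = cat["N"] * cat["FREQ_A1"]

    g = cat.groupby("SNP", sort=False)
    sw = g["_w"].sum()
    beta = g["_wb"].sum() / sw
    se = 1.0 / np.sqrt(sw)
    n_total = g["N"].sum()
    n_studies = g["_w"].size()
    first = g[["CHR", "POS", "A1", "A2"]].first()
    freq = g["_wf"].sum() / n_total

    cat["_beta_meta"] = beta.reindex(cat["SNP"]).to_numpy()
    q = cat.assign(_q=cat["_w"] * (cat["BETA"] - cat["_beta_meta"]) ** 2).groupby(
        "SNP", sort=False
    )["_q"].sum()
    direction = g["BETA"].agg(
        lambda b: "".join("+" if x > 0 else "-" if x < 0 else "0" for x in b)
    )

    z = (beta / se).to_numpy()
    p, flag = floor_pvalues(2.0 * stats.norm.sf(np.abs(z)))
    out = pd.DataFrame(
        {
            "SNP": beta.index,
            "CHR": first["CHR"].to_numpy(),
            "POS": first["POS"].to_numpy(),
            "A1": first["A1"].to_numpy(),
            "A2": first["A2"].to_numpy(),
            "FREQ_A1": freq.to_numpy(),
            "BETA": beta.to_numpy(),
            "SE": se.to_numpy(),
            "P": p,
            "P_UNDERFLOW": flag,
            "N": n_total.to_numpy(),
            "INFO": 1.0,
            "N_STUDIES": n_studies.to_numpy(),
            "Q": q.reindex(beta.index).to_numpy(),
            "DIRECTION": direction.reindex(beta.index).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def zscore_meta(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size-weighted z-score meta-analysis.

    ``z_meta = sum(z_i sqrt(n_i)) / sqrt(sum n_i)`` with per-study
    ``z_i = BETA_i / SE_i`` (alignment signs are assumed already applied).
    Variants missing a sample size are omitted.
    """
    cat = _stack(studies)
    cat = cat[np.isfinite(cat["N"]) & (cat["N"] > 0)]
    cat["_z"] = cat["BETA"] / cat["SE"]
    cat["_zsn"] = cat["_z"] * np.sqrt(cat["N"])
    g = cat.groupby("SNP", sort=False)
    n_total = g["N"].sum()
    z_meta = g["_zsn"].sum() / np.sqrt(n_total)
    first = g[["CHR", "POS", "A1", "A2"]].first()
    freq = (g.apply(lambda d: float((d["N"] * d["FREQ_A1"]).sum() / d["N"].sum()), include_groups=False)
            if len(cat) else pd.Series(dtype=float))
    p, flag = floor_pvalues(2.0 * stats.norm.sf(np.abs(z_meta.to_numpy())))
    direction = g["BETA"].agg(
        lambda b: "".join("+" if x > 0 else "-" if x < 0 else "0" for x in b)
    )
    out = pd.DataFrame(
        {
            "SNP": z_meta.index,
            "CHR": first["CHR"].to_numpy(),
            "POS": first["POS"].to_numpy(),
            "A1": first["A1"].to_numpy(),
            "A2": first["A2"].to_numpy(),
            "FREQ_A1": freq.reindex(z_meta.index).to_numpy(),
            "Z": z_meta.to_numpy(),
            "P": p,
            "P_UNDERFLOW": flag,
            "N": n_total.to_numpy(),
            "N_STUDIES": g["_z"].size().to_numpy(),
            "DIRECTION": direction.reindex(z_meta.index).to_numpy(),
        }
    )
    return out.reset_index(drop=True)
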