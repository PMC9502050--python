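"""Per-cohort GWAS stage: phenotype transformation, association scan, QC.

The skewed biomarker is rank-based inverse-normal transformed before
association (Blom offset 3/8, average ranks for ties). Association is
additive OLS of the transformed phenotype on dosage, optionally adjusting
for covariates via Frisch-Waugh-Lovell residualization; p-values come from
the normal approximation to the t statistic, matching downstream
summary-statistics conventions. Relatedness is not modelled: samples are
unrelated by construction in the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, NumericalDesignError, SchemaError
from .simulate import GenotypeMatrix
from .sumstats import SUMSTATS_COLUMNS, floor_pvalues

BLOM_OFFSET = 3.0 / 8.0


def inverse_normal_transform(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps value with rank r (average ranks on ties) to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``. Preserves rank order;
    output is approximately standard normal.

    Raises
    ------
    DegenerateInputError
        If fewer than two distinct values are present.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D phenotype vector")
    if len(np.unique(x)) < 2:
        raise DegenerateInputError("phenotype has fewer than two distinct values")
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def _residualize(y: np.ndarray, G: np.ndarray, covariates) -> tuple[np.ndarray, np.ndarray, int]:
    """Project phenotype and dosages off [1, covariates]; return adjusted df count."""
    n = len(y)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return y - y.mean(), G - G.mean(axis=0), 0
    C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise NumericalDesignError("covariate matrix is rank deficient")
    Q, _ = np.linalg.qr(C)
    return y - Q @ (Q.T @ y), G - Q @ (Q.T @ G), C.shape[1] - 1


def association_scan(
    genotypes: GenotypeMatrix, phenotype, covariates=None
) -> pd.DataFrame:
    """Additive per-variant regression of phenotype on dosage.

    Returns a summary-statistics table (one row per panel variant) with the
    slope, its SE, the two-sided normal-approximation p-value, the in-sample
    effect-allele frequency and the sample size.
    """
    y = np.asarray(phenotype, dtype=float)
    G = genotypes.dosages.astype(float)
    n = genotypes.n_samples
    if len(y) != n:
        raise SchemaError("phenotype length does not match genotype sample count")
    yr, Gr, k = _residualize(y, G, covariates)
    sxx = np.einsum("ij,ij->j", Gr, Gr)
    sxy = Gr.T @ yr
    syy = float(yr @ yr)
    if np.any(sxx <= 0):
        raise DegenerateInputError("monomorphic variant in the scan panel")
    beta = sxy / sxx
    dof = max(n - 2 - k, 1)
    sigma2 = np.maximum(syy - beta * sxy, 0.0) / dof
    se = np.sqrt(np.maximum(sigma2, 1e-300) / sxx)
    z = beta / se
    p, flag = floor_pvalues(2.0 * stats.norm.sf(np.abs(z)))
    out = genotypes.panel.copy()
    out["FREQ_A1"] = genotypes.sample_freqs()
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    out["P_UNDERFLOW"] = flag
    out["N"] = n
    out["INFO"] = 1.0
    return out[SUMSTATS_COLUMNS + ["P_UNDERFLOW"]]


@dataclass
class QCThresholds:
    """Variant-level QC: pre-meta MAC/EAF/Info filters, post-meta MAF filter."""

    mac_min: int = 3          # strict: keep MAC > mac_min
    info_min: float = 0.3     # keep Info >= info_min
    eaf_bounds: tuple[float, float] = (0.0, 1.0)  # keep lo < EAF < hi
    maf_min: float = 0.01     # post-meta: keep MAF >= maf_min

    def __post_init__(self):
        if self.mac_min < 0:
            raise ValueError("mac_min must be >= 0")
        if not (0 <= self.info_min <= 1):
            raise ValueError("info_min must lie in [0, 1]")


def qc_filter(
    stats_df: pd.DataFrame, thresholds: QCThresholds, stage: str = "pre_meta"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply variant QC; return (surviving rows, exclusion log).

    ``pre_meta`` applies the minor-allele-count (strict >), effect-allele
    frequency and imputation-Info filters; ``post_meta`` applies the
    symmetric minor-allele-frequency filter ``min(f, 1-f) >= maf_min``.
    Survivors preserve input order; every exclusion is logged with a reason.
    """
    if stage not in ("pre_meta", "post_meta"):
        raise ValueError(f"unknown QC stage: {stage}")
    if len(stats_df) == 0:
        raise SchemaError("empty summary-statistics table")
    f = stats_df["FREQ_A1"].to_numpy(float)
    maf = np.minimum(f, 1.0 - f)
    reasons = pd.Series([""] * len(stats_df), index=stats_df.index)
    if stage == "pre_meta":
        mac = 2.0 * stats_df["N"].to_numpy(float) * maf
        lo, hi = thresholds.eaf_bounds
        reasons[mac <= thresholds.mac_min] = f"MAC <= {thresholds.mac_min}"
        reasons[(f <= lo) | (f >= hi)] = "EAF outside bounds"
        reasons[stats_df["INFO"].to_numpy(float) < thresholds.info_min] = (
            f"Info < {thresholds.info_min}"
        )
    else:
        reasons[maf < thresholds.maf_min] = f"MAF < {thresholds.maf_min}"
    excluded = reasons != ""
    log = pd.DataFrame(
        {"snp_id": stats_df.loc[excluded, "SNP"], "reason": reasons[excluded]}
    ).reset_index(drop=True)
    return stats_df[~excluded].reset_index(drop=True), log
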