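"""Stepwise conditional and joint association analysis from summary statistics.

Approximates multiple regression of the phenotype on a set of variants using
only marginal summary statistics plus an LD reference, in the conditional /
joint framework popularised by GCTA-COJO: the X'X block for a variant set is
reconstructed as ``D^(1/2) R D^(1/2)`` with ``D_j = var(dosage_j) * n_j``
(per-variant effective sample sizes are respected via the diagonal), and
``X'y_j = D_j * beta_marginal_j``. When the LD correlations and dosage
variances come from the same sample as the summary statistics, the joint
solution reproduces individual-level multiple regression coefficients
exactly — the module's primary oracle.

Forward selection seeds with the smallest marginal p below the significance
threshold, repeatedly adds the most significant conditional candidate, and
drops variants whose joint p rises back above the threshold. Candidates in
strong LD (r^2 above the collinearity cutoff) with any selected variant are
excluded from candidacy; reference correlations beyond the LD window are
treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError
from .ld import LDMatrix

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_COLLINEARITY_R2 = 0.9
DEFAULT_WINDOW_BP = 10_000_000


@dataclass
class CojoResult:
    """Outcome of the stepwise selection."""

    selected: list[str]
    joint: pd.DataFrame              # SNP, JOINT_BETA, JOINT_SE, JOINT_P
    trace: list[dict] = field(default_factory=list)
    p_threshold: float = DEFAULT_P_THRESHOLD
    excluded: pd.DataFrame | None = None   # collinearity exclusions


class _Workspace:
    """Marginal statistics aligned to the LD panel, with windowed R."""

    def __init__(self, marginal: pd.DataFrame, ld: LDMatrix, window_bp: float):
        in_ld = set(ld.variant_ids)
        sub = marginal[marginal["SNP"].isin(in_ld)].reset_index(drop=True)
        idx = ld.index_of(sub["SNP"])
        self.snp = sub["SNP"].to_numpy()
        self.pos = sub["POS"].to_numpy(float)
        self.b = sub["BETA"].to_numpy(float)
        self.se = sub["SE"].to_numpy(float)
        self.n = sub["N"].to_numpy(float)
        f = sub["FREQ_A1"].to_numpy(float)
        if ld.var_dosage is not None:
            var = np.asarray(ld.var_dosage)[idx]
        else:
            var = 2.0 * f * (1.0 - f)
        self.D = var * self.n
        R = ld.r[np.ix_(idx, idx)].copy()
        far = np.abs(self.pos[:, None] - self.pos[None, :]) > window_bp
        R[far] = 0.0
        np.fill_diagonal(R, 1.0)
        self.R = R
        self.Xy = self.D * self.b
        # Per-variant implied total sum of squares of the (unit-variance) phenotype.
        self.syy = self.D * (self.se**2 * (self.n - 2.0) + self.b**2)
        self.z = self.b / self.se
        self.m = len(self.snp)

    def loc(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp)}
        return np.array([lookup[i] for i in ids], dtype=int)

    def xtx(self, idx: np.ndarray) -> np.ndarray:
        d = np.sqrt(self.D[idx])
        return self.R[np.ix_(idx, idx)] * np.outer(d, d)


def _solve_joint(ws: _Workspace, idx: np.ndarray):
    """Joint betas/SEs/p for the variant set ``idx`` (workspace indices)."""
    B = ws.xtx(idx)
    if np.linalg.cond(B) > 1e12:
        sub_r = np.abs(ws.R[np.ix_(idx, idx)] - np.eye(len(idx)))
        i, j = np.unravel_index(np.argmax(sub_r), sub_r.shape)
        raise CollinearityError(
            f"singular LD submatrix for selected set; offending pair "
            f"{ws.snp[idx[i]]} / {ws.snp[idx[j]]} (r={ws.R[idx[i], idx[j]]:.4f})"
        )
    Binv = np.linalg.inv(B)
    beta = Binv @ ws.Xy[idx]
    p = len(idx)
    n_eff = float(np.median(ws.n[idx]))
    syy = float(np.median(ws.syy[idx]))
    sigma2 = max(syy - float(beta @ ws.Xy[idx]), 0.0) / max(n_eff - p - 1.0, 1.0)
    se = np.sqrt(np.maximum(sigma2, 1e-300) * np.diag(Binv))
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, pvals, Binv


def joint_fit(
    marginal: pd.DataFrame,
    selected: list[str],
    ld: LDMatrix,
    window_bp: float = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Jointly refit a selected variant set from summary data.

    Solves the normal equations reconstructed from the LD reference. A
    singleton set reproduces the marginal statistics; with exact in-sample
    LD the coefficients equal individual-level multiple regression.

    Raises
    ------
    CollinearityError
        If the selected-set LD submatrix is singular, naming the worst pair.
    """
    ws = _Workspace(marginal, ld, window_bp)
    idx = ws.loc(selected)
    beta, se, pvals, _ = _solve_joint(ws, idx)
    return pd.DataFrame(
        {"SNP": list(selected), "JOINT_BETA": beta, "JOINT_SE": se, "JOINT_P": pvals}
    )


def _conditional(ws: _Workspace, sel_idx: np.ndarray, cand_idx: np.ndarray):
    """Conditional beta/se/p for each candidate given the selected set.

    Each candidate is fit jointly with the selected set; its coefficient is
    the conditional effect. The conditional SE uses the candidate's own
    marginal residual variance (conservative under LD; exact under
    orthogonality, where conditional and marginal statistics coincide).
    """
    betas = np.full(len(cand_idx), np.nan)
    ses = np.full(len(cand_idx), np.nan)
    for k, j in enumerate(cand_idx):
        idx = np.append(sel_idx, j)
        B = ws.xtx(idx)
        Binv = np.linalg.inv(B)
        coef = Binv @ ws.Xy[idx]
        sigma2_j = ws.D[j] * ws.se[j] ** 2
        betas[k] = coef[-1]
        ses[k] = np.sqrt(max(sigma2_j, 1e-300) * Binv[-1, -1])
    pvals = 2.0 * stats.norm.sf(np.abs(betas / ses))
    return betas, ses, pvals


def conditional_stats(
    marginal: pd.DataFrame,
    selected: list[str],
    ld: LDMatrix,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    window_bp: float = DEFAULT_WINDOW_BP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-candidate conditional statistics given a selected set.

    Candidates whose reference r^2 with any selected variant exceeds the
    collinearity cutoff are excluded from candidacy and logged, never
    returning a conditional value. Returns (conditional table, exclusion
    log).
    """
    ws = _Workspace(marginal, ld, window_bp)
    sel_idx = ws.loc(selected)
    mask = np.ones(ws.m, dtype=bool)
    mask[sel_idx] = False
    r2_vs_sel = (
        (ws.R[:, sel_idx] ** 2).max(axis=1) if len(sel_idx) else np.zeros(ws.m)
    )
    collinear = mask & (r2_vs_sel > collinearity_r2)
    cand_idx = np.where(mask & ~collinear)[0]
    if len(sel_idx):
        betas, ses, pvals = _conditional(ws, sel_idx, cand_idx)
    else:
        betas, ses, pvals = ws.b[cand_idx], ws.se[cand_idx], (
            2.0 * stats.norm.sf(np.abs(ws.z[cand_idx]))
        )
    table = pd.DataFrame(
        {
            "SNP": ws.snp[cand_idx],
            "COND_BETA": betas,
            "COND_SE": ses,
            "COND_P": pvals,
        }
    )
    log = pd.DataFrame(
        {
            "snp_id": ws.snp[collinear],
            "reason": [f"r2 > {collinearity_r2} with selected set"]
            * int(collinear.sum()),
        }
    )
    return table, log


def _best(ws: _Workspace, idx: np.ndarray, zabs: np.ndarray) -> int:
    """Most significant candidate (largest |z|); ties go to smaller position."""
    order = np.lexsort((ws.pos[idx], -zabs))
    return int(idx[order[0]])


def stepwise_select(
    marginal: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    window_bp: float = DEFAULT_WINDOW_BP,
    max_selected: int = 50,
) -> CojoResult:
    """Forward stepwise selection of independently associated variants.

    Seeds with the smallest marginal p below ``p_threshold``; at each step
    adds the most significant conditional candidate below threshold, then
    jointly refits and drops any variant whose joint p rises above the
    threshold. Deterministic: ties on p go to the smaller position. An
    empty selection (no variant below threshold) is a legal result.
    """
    ws = _Workspace(marginal, ld, window_bp)
    trace: list[dict] = []
    excl_frames = []
    marg_p = 2.0 * stats.norm.sf(np.abs(ws.z))

    all_idx = np.arange(ws.m)
    if ws.m == 0 or marg_p.min() >= p_threshold:
        return CojoResult([], pd.DataFrame(columns=["SNP", "JOINT_BETA", "JOINT_SE", "JOINT_P"]),
                          trace, p_threshold)

    sel = [_best(ws, all_idx, np.abs(ws.z))]
    trace.append({"step": 0, "added": ws.snp[sel[0]], "p": float(marg_p[sel[0]])})

    step = 0
    while len(sel) < max_selected:
        step += 1
        sel_idx = np.array(sel, dtype=int)
        mask = np.ones(ws.m, dtype=bool)
        mask[sel_idx] = False
        r2_vs_sel = (ws.R[:, sel_idx] ** 2).max(axis=1)
        collinear = mask & (r2_vs_sel > collinearity_r2)
        if collinear.any():
            excl_frames.append(
                pd.DataFrame({"snp_id": ws.snp[collinear],
                              "reason": f"r2 > {collinearity_r2} with selected set",
                              "step": step})
            )
        cand_idx = np.where(mask & ~collinear)[0]
        if len(cand_idx) == 0:
            break
        cond_b, cond_se, cond_p = _conditional(ws, sel_idx, cand_idx)
        zabs = np.abs(cond_b / cond_se)
        finite = np.isfinite(cond_p)
        if not finite.any() or cond_p[finite].min() >= p_threshold:
            break
        best = _best(ws, cand_idx[finite], zabs[finite])
        sel.append(best)
        trace.append(
            {"step": step, "added": ws.snp[best],
             "p": float(cond_p[finite][list(cand_idx[finite]).index(best)])}
        )
        # Backward check: drop variants no longer jointly significant.
        while len(sel) > 1:
            jb, jse, jp, _ = _solve_joint(ws, np.array(sel, dtype=int))
            worst = int(np.argmax(jp))
            if jp[worst] < p_threshold:
                break
            dropped = sel.pop(worst)
            trace.append({"step": step, "dropped": ws.snp[dropped],
                          "p": float(jp[worst])})

    sel_ids = [ws.snp[i] for i in sel]
    jb, jse, jp, _ = _solve_joint(ws, np.array(sel, dtype=int))
    joint = pd.DataFrame(
        {"SNP": sel_ids, "JOINT_BETA": jb, "JOINT_SE": jse, "JOINT_P": jp}
    )
    excluded = (
        pd.concat(excl_frames, ignore_index=True)
        if excl_frames
        else pd.DataFrame(columns=["snp_id", "reason", "step"])
    )
    return CojoResult(sel_ids, joint, trace, p_threshold, excluded)
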