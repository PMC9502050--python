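"""Approximate-Bayes-factor colocalization of two regional association signals.

Under a single-causal-variant assumption per trait, the evidence that
variant i drives a trait is summarised by the Wakefield approximate Bayes
factor computed from the marginal effect and its standard error. Posterior
probabilities are then assigned to five hypotheses for the region:

    H0  neither trait associated
    H1  trait 1 only
    H2  trait 2 only
    H3  both traits, distinct causal variants
    H4  both traits, one shared causal variant

with per-variant priors p1, p2 (trait-specific causality) and p12 (shared
causality). All sums are evaluated in log space so that z-scores into the
tens do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import SchemaError
from . import meta

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
DEFAULT_PRIOR_SD = (0.15, 0.15)
HYPOTHESES = ("PP0", "PP1", "PP2", "PP3", "PP4")


def wakefield_log_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association at one variant.

    With ``V = se^2``, ``W = prior_sd^2``, ``z = beta/se`` and shrinkage
    ``r = W/(V+W)``:  ``log ABF = 0.5*log(1-r) + z^2 * r / 2``, oriented so
    larger values mean stronger evidence of association. A degenerate prior
    (``prior_sd -> 0``) yields 0: no evidence either way.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


@dataclass
class ColocResult:
    """Posterior probabilities PP0-PP4 plus per-variant log-ABFs."""

    pp: np.ndarray                  # length 5, sums to 1
    snps: list[str]
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    n_variants: int

    def __getitem__(self, key: str) -> float:
        return float(self.pp[HYPOTHESES.index(key)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hypothesis": HYPOTHESES, "posterior": self.pp})

    def abf_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SNP": self.snps, "LOG_ABF_TRAIT1": self.log_abf1,
             "LOG_ABF_TRAIT2": self.log_abf2}
        )


def _posteriors_from_log_abf(l1, l2, priors) -> np.ndarray:
    p1, p2, p12 = priors
    if not (0 < p12 <= min(p1, p2) < 1):
        raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + s1
    lh[2] = np.log(p2) + s2
    # H3 sums over ordered distinct pairs: S1*S2 minus the diagonal, stably.
    diff = s12 - (s1 + s2)
    if diff >= -1e-14:
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + s1 + s2 + np.log1p(-np.exp(diff))
    lh[4] = np.log(p12) + s12
    pp = np.exp(lh - logsumexp(lh))
    return pp / pp.sum()


def intersect_and_align(
    trait1: pd.DataFrame, trait2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Intersect two regional tables on chrom:pos and align trait2's alleles.

    Returns (trait1 subset, aligned trait2 subset, drop log); both outputs
    share an identical variant order.
    """
    aligned2, log = meta.align_alleles(trait2, trait1)
    common = pd.Index(trait1["SNP"]).intersection(aligned2["SNP"])
    t1 = trait1.set_index("SNP").loc[common].reset_index()
    t2 = aligned2.set_index("SNP").loc[common].reset_index()
    return t1, t2, log


def coloc_posteriors(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd: tuple[float, float] = DEFAULT_PRIOR_SD,
    align: bool = True,
    p_filter_trait2: float | None = None,
) -> ColocResult:
    """Colocalization posteriors for two traits over one region.

    ``p_filter_trait2`` optionally pre-filters trait-2 variants by p-value
    (emulating an FDR-screened eQTL input); off by default, as filtering
    coloc inputs is nonstandard.
    """
    if align:
        t1, t2, _ = intersect_and_align(trait1, trait2)
    else:
        t1, t2 = trait1.reset_index(drop=True), trait2.reset_index(drop=True)
    if p_filter_trait2 is not None:
        keep = t2["P"] <= p_filter_trait2
        t1, t2 = t1[keep.to_numpy()], t2[keep.to_numpy()]
    if len(t1) < 2:
        raise SchemaError("fewer than two shared variants after alignment")
    l1 = wakefield_log_abf(t1["BETA"].to_numpy(), t1["SE"].to_numpy(), prior_sd[0])
    l2 = wakefield_log_abf(t2["BETA"].to_numpy(), t2["SE"].to_numpy(), prior_sd[1])
    pp = _posteriors_from_log_abf(l1, l2, priors)
    return ColocResult(pp, list(t1["SNP"]), l1, l2, len(t1))


def restrict_window(stats_df: pd.DataFrame, center_pos: int, window_bp: int) -> pd.DataFrame:
    """Keep variants within ``window_bp`` of a center position (closed interval)."""
    pos = stats_df["POS"].to_numpy(float)
    return stats_df[np.abs(pos - center_pos) <= window_bp].reset_index(drop=True)


def plot_miami(trait1: pd.DataFrame, trait2: pd.DataFrame, path,
               highlight: str | None = None) -> None:
    """Mirrored regional association plot: trait 1 up, trait 2 down."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    ax.scatter(trait1["POS"] / 1e6, -np.log10(trait1["P"]), s=8, c="firebrick",
               label="trait 1")
    ax.scatter(trait2["POS"] / 1e6, np.log10(trait2["P"]), s=8, c="steelblue",
               label="trait 2")
    for y in (-np.log10(5e-8), np.log10(5e-8)):
        ax.axhline(y, ls="--", lw=0.8, c="grey")
    ax.axhline(0, lw=0.8, c="black")
    if highlight is not None:
        hit = trait1[trait1["SNP"] == highlight]
        if len(hit):
            ax.scatter(hit["POS"] / 1e6, -np.log10(hit["P"]), marker="D", s=60,
                       c="black", label=highlight)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"signed $-\log_{10}(p)$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
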