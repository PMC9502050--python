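"""Synthetic multi-cohort genotype/phenotype data and summary statistics.

Emulates the statistical structure the downstream analyses assume: four
cohorts measuring a right-skewed circulating biomarker driven by a single
cis-acting causal variant, binary-outcome GWAS summary statistics consistent
with a variant -> exposure -> outcome mediation model, and regional eQTL
summary statistics with a causal variant either shared with or distinct from
the biomarker's.

Genotypes are drawn from Hardy-Weinberg proportions with linkage
disequilibrium induced by thresholding latent Gaussian haplotypes with AR(1)
correlation: the latent correlation between variants i and j is
``rho**|i-j|`` with ``rho = 0.5**(1/ld_decay)``, so ``ld_decay`` is the
index distance at which latent correlation halves. Every generator is a
pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .sumstats import SUMSTATS_COLUMNS, floor_pvalues

# Default cohort sizes: InCHIANTI, PREVEND, BLSA, HealthABC (pooled n = 6,127).
DEFAULT_COHORTS = (1210, 2954, 458, 1505)
COHORT_NAMES = ("InCHIANTI", "PREVEND", "BLSA", "HealthABC")

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic region.

    Defaults reproduce the design of the biomarker meta-analysis: four
    cohorts of 1,210 / 2,954 / 458 / 1,505 samples and a causal per-allele
    effect of 0.063 phenotype-SD.
    """

    n_per_cohort: tuple[int, ...] = DEFAULT_COHORTS
    n_variants: int = 120
    causal_index: int = 60
    beta_causal: float = 0.063
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 10.0
    skew: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_cohort) < 1 or any(n < 1 for n in self.n_per_cohort):
            raise ConfigurationError("all cohort sample counts must be >= 1")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("maf_range bounds must lie strictly inside (0, 1)")
        if self.ld_decay <= 0:
            raise ConfigurationError("ld_decay must be > 0")
        if not (0 <= self.causal_index < self.n_variants):
            raise IndexError("causal_index outside the variant panel")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_cohort))


@dataclass
class GenotypeMatrix:
    """Additive dosage codes (0/1/2) with the accompanying variant panel."""

    dosages: np.ndarray          # (n_samples, n_variants) int8
    panel: pd.DataFrame          # SNP, CHR, POS, A1, A2, FREQ_A1

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def sample_freqs(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class TrialEffect:
    """Trial-induced biomarker change: median change and baseline SD, both IU/L."""

    median_change: float = 27.1
    baseline_sd: float = 61.0

    def __post_init__(self):
        if self.baseline_sd <= 0:
            raise ConfigurationError("baseline_sd must be > 0")


def make_panel(config: SimulationConfig, freqs: np.ndarray) -> pd.DataFrame:
    """Variant panel for a cis region on chromosome 7 (EPO promoter locus)."""
    m = config.n_variants
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    return pd.DataFrame(
        {
            "SNP": [f"rs{900000 + i}" for i in range(m)],
            "CHR": ["7"] * m,
            "POS": 100_317_298 + (np.arange(m) - config.causal_index) * 5_000,
            "A1": [a for a, _ in alleles],
            "A2": [b for _, b in alleles],
            "FREQ_A1": freqs,
        }
    )


def _draw_dosages(rng, n, freqs, rho) -> np.ndarray:
    """Two latent-Gaussian haplotypes per sample, thresholded at Phi^-1(f)."""
    m = len(freqs)
    thr = stats.norm.ppf(freqs)
    dos = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):  # two haplotypes -> HWE at each variant
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(n)
        dos += (z < thr).astype(np.int8)
    return dos


def panel_freqs(config: SimulationConfig) -> np.ndarray:
    """Population allele frequencies of the panel.

    Drawn uniformly in ``maf_range`` from ``config.seed`` alone, so every
    cohort simulated under one configuration shares the same panel.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_variants)


def simulate_genotypes(
    config: SimulationConfig, n_samples: int | None = None, seed: int | None = None
) -> GenotypeMatrix:
    """Simulate a genotype matrix for the regional panel.

    Allele frequencies come from :func:`panel_freqs`; dosages follow
    Hardy-Weinberg proportions with geometrically decaying LD. Monomorphic
    columns (possible at small n) are redrawn independently so every variant
    is polymorphic in-sample.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 1])
    n = config.n_total if n_samples is None else int(n_samples)
    if n < 1:
        raise ConfigurationError("n_samples must be >= 1")
    freqs = panel_freqs(config)
    rho = 0.5 ** (1.0 / config.ld_decay)
    dos = _draw_dosages(rng, n, freqs, rho)
    for _ in range(100):
        f_hat = dos.mean(axis=0) / 2.0
        bad = (f_hat <= 0.0) | (f_hat >= 1.0)
        if not bad.any():
            break
        dos[:, bad] = _draw_dosages(rng, n, freqs[bad], 0.0)
    return GenotypeMatrix(dosages=dos, panel=make_panel(config, freqs))


def skewed_noise(rng, n: int, skew: float) -> np.ndarray:
    """Mean-zero unit-variance noise from a shifted log-normal.

    ``skew`` is the log-scale sigma; ``skew=0`` degenerates to a standard
    normal. Closed-form skewness of the family:
    ``(exp(s^2) + 2) * sqrt(exp(s^2) - 1)``.
    """
    if skew == 0:
        return rng.standard_normal(n)
    x = np.exp(skew * rng.standard_normal(n))
    mu = np.exp(skew**2 / 2.0)
    sd = np.sqrt((np.exp(skew**2) - 1.0) * np.exp(skew**2))
    return (x - mu) / sd


def lognormal_skewness(skew: float) -> float:
    """Closed-form skewness of the shifted log-normal noise family."""
    e = np.exp(skew**2)
    return float((e + 2.0) * np.sqrt(e - 1.0))


def simulate_biomarker(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed: int | None = None
) -> np.ndarray:
    """Right-skewed biomarker driven by the causal variant.

    phenotype = beta_causal * dosage(causal) + unit-variance skewed noise,
    so the per-allele effect is on the (approximate) phenotype-SD scale and
    recoverable by regression.
    """
    if not (0 <= config.causal_index < genotypes.n_variants):
        raise IndexError("causal_index outside the genotype panel")
    rng = np.random.default_rng([config.seed if seed is None else seed, 2])
    g = genotypes.dosages[:, config.causal_index].astype(float)
    return config.beta_causal * g + skewed_noise(rng, genotypes.n_samples, config.skew)


def simulate_cohorts(config: SimulationConfig) -> list[dict]:
    """Simulate all cohorts: genotypes plus biomarker per cohort.

    Cohort ``i`` uses seeds derived deterministically from ``config.seed``.
    Returns a list of dicts with keys ``name``, ``genotypes``, ``phenotype``.
    """
    names = list(COHORT_NAMES[: len(config.n_per_cohort)])
    names += [f"cohort{i}" for i in range(len(names), len(config.n_per_cohort))]
    out = []
    for i, n in enumerate(config.n_per_cohort):
        gt = simulate_genotypes(config, n_samples=n, seed=config.seed + i + 1)
        ph = simulate_biomarker(gt, config, seed=config.seed + i + 1)
        out.append({"name": names[i], "genotypes": gt, "phenotype": ph})
    return out


def expected_marginal_exposure_betas(
    panel: pd.DataFrame,
    beta_exposure_sd: float,
    causal_index: int,
    r_causal: np.ndarray | None = None,
) -> np.ndarray:
    """Expected per-allele marginal exposure effects across the panel.

    A variant in LD r with the causal variant has marginal slope
    ``beta_causal * r * sd(causal) / sd(variant)``. With ``r_causal=None``
    only the causal variant itself has a nonzero effect.
    """
    m = len(panel)
    freqs = panel["FREQ_A1"].to_numpy(float)
    var = 2.0 * freqs * (1.0 - freqs)
    if r_causal is None:
        r_causal = np.zeros(m)
        r_causal[causal_index] = 1.0
    return beta_exposure_sd * r_causal * np.sqrt(var[causal_index] / var)


def simulate_outcome_summary(
    panel: pd.DataFrame,
    true_causal_or: float,
    beta_exposure_sd: float,
    causal_index: int,
    n_cases: int,
    n_controls: int,
    seed: int,
    r_causal: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binary-outcome GWAS summary statistics under exposure mediation.

    The expected per-allele log-odds at each variant is
    ``ln(true_causal_or) * beta_exposure(variant)``; standard errors use the
    binary-trait approximation ``1/sqrt(2 f (1-f) n_eff)`` with
    ``n_eff = 4 / (1/cases + 1/controls)``, and independent Gaussian noise
    is added per seed.
    """
    if true_causal_or <= 0:
        raise ConfigurationError("true_causal_or must be > 0")
    if n_cases < 1 or n_controls < 1:
        raise ConfigurationError("case and control counts must be >= 1")
    rng = np.random.default_rng([seed, 3])
    freqs = panel["FREQ_A1"].to_numpy(float)
    var = 2.0 * freqs * (1.0 - freqs)
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    se = 1.0 / np.sqrt(var * n_eff)
    expected = np.log(true_causal_or) * expected_marginal_exposure_betas(
        panel, beta_exposure_sd, causal_index, r_causal
    )
    beta = expected + rng.standard_normal(len(panel)) * se
    z = beta / se
    p, flag = floor_pvalues(2.0 * stats.norm.sf(np.abs(z)))
    out = panel.copy()
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    out["P_UNDERFLOW"] = flag
    out["N"] = n_cases + n_controls
    out["INFO"] = 1.0
    return out[SUMSTATS_COLUMNS + ["P_UNDERFLOW"]]


def simulate_eqtl_summary(
    config: SimulationConfig,
    shared_causal: bool = True,
    effect_size: float = 0.3,
    n: int = 861,
    seed: int | None = None,
    distinct_index: int | None = None,
) -> pd.DataFrame:
    """Regional eQTL summary statistics, simulated at individual level.

    When ``shared_causal`` the expression causal variant is the biomarker's
    (``config.causal_index``), the ground truth for colocalization H4;
    otherwise a distinct variant is causal (``distinct_index``, defaulting to
    the first panel variant), the H3 truth. Expression noise is standard
    normal.
    """
    seed = config.seed + 77 if seed is None else seed
    gt = simulate_genotypes(config, n_samples=n, seed=seed)
    causal = config.causal_index if shared_causal else distinct_index
    if causal is None:
        causal = 0
    rng = np.random.default_rng([seed, 4])
    expr = effect_size * gt.dosages[:, causal].astype(float) + rng.standard_normal(n)
    from .gwas import association_scan  # local import: avoids module cycle

    return association_scan(gt, expr)
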