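"""Single-instrument Wald-ratio Mendelian randomization and trial rescaling.

The causal effect of the exposure (circulating biomarker, SD units) on an
outcome is estimated with one cis instrument as the ratio of the per-allele
outcome effect to the per-allele exposure effect, with a delta-method SE.
Genetic per-SD estimates are then (a) converted between SD and natural
units (IU/L) and (b) rescaled to the exposure change induced by a clinical
trial: a trial shifting the biomarker by ``median_change / baseline_sd``
SD corresponds to multiplying log-odds (or linear) effects and their CI
bounds by that SD fraction, i.e. raising odds ratios to that power. The
rescaled upper confidence bound in the harm direction is reported as the
largest adverse effect the genetic data can exclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, WeakInstrumentError
from .simulate import TrialEffect

Z95 = stats.norm.ppf(0.975)


@dataclass
class WaldEstimate:
    """Instrument-based causal effect per exposure SD."""

    ratio: float
    se_ratio: float
    ci: tuple[float, float]
    instrument: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    method: str = "first_order"
    binary_outcome: bool = True

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.ratio / self.se_ratio)))

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, lower, upper) — the exact exponential image of the log scale."""
        return (np.exp(self.ratio), np.exp(self.ci[0]), np.exp(self.ci[1]))


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    method: str = "first_order",
    instrument: str = "",
    binary_outcome: bool = True,
) -> WaldEstimate:
    """Wald ratio estimate with first- or second-order delta-method SE.

    first_order: ``SE = se_out / |beta_exp|`` (exposure treated as known);
    second_order adds the exposure-uncertainty term:
    ``sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4)``.

    Raises
    ------
    WeakInstrumentError
        If the exposure effect is zero.
    """
    if beta_exposure == 0:
        raise WeakInstrumentError("instrument has zero exposure effect")
    if method not in ("first_order", "second_order"):
        raise ValueError(f"unknown SE method: {method}")
    ratio = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    if method == "second_order":
        se = np.sqrt(
            se_outcome**2 / beta_exposure**2
            + beta_outcome**2 * se_exposure**2 / beta_exposure**4
        )
    ci = (ratio - Z95 * se, ratio + Z95 * se)
    return WaldEstimate(
        ratio=float(ratio), se_ratio=float(se), ci=ci, instrument=instrument,
        beta_exposure=beta_exposure, se_exposure=se_exposure,
        beta_outcome=beta_outcome, se_outcome=se_outcome,
        method=method, binary_outcome=binary_outcome,
    )


def combine_outcome_sources(stats_a: dict, stats_b: dict | None = None) -> dict:
    """IVW-pool the instrument's outcome association across sources.

    Each source is a mapping with keys ``beta`` and ``se`` (optionally
    ``n``). A single source is returned unchanged.
    """
    if stats_b is None:
        return dict(stats_a)
    w = np.array([1.0 / stats_a["se"] ** 2, 1.0 / stats_b["se"] ** 2])
    b = np.array([stats_a["beta"], stats_b["beta"]])
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    n = stats_a.get("n", 0) + (stats_b.get("n", 0) if stats_b else 0)
    return {"beta": beta, "se": se, "n": n}


@dataclass
class UnitMap:
    """Natural units of one exposure SD (IU/L per SD)."""

    sd_in_natural_units: float = 5.1

    def __post_init__(self):
        if self.sd_in_natural_units <= 0:
            raise ConfigurationError("sd_in_natural_units must be positive")


def convert_units(beta_sd: float, unit_map: UnitMap) -> float:
    """SD-scale effect -> natural units (sign preserving)."""
    return beta_sd * unit_map.sd_in_natural_units


def scaling_factor(trial: TrialEffect, beta_exposure_sd: float) -> tuple[float, float]:
    """Trial-anchored rescaling of a per-allele genetic effect.

    ``scaling_sd = median_change / baseline_sd`` is the trial-induced
    exposure change in SD; ``factor = scaling_sd / beta_exposure_sd`` is
    the number of effect-allele copies the trial effect corresponds to.
    Returns (factor, scaling_sd).
    """
    if trial.baseline_sd <= 0:
        raise ConfigurationError("baseline_sd must be positive")
    if beta_exposure_sd == 0:
        raise WeakInstrumentError("zero exposure effect cannot be rescaled")
    scaling_sd = trial.median_change / trial.baseline_sd
    return scaling_sd / beta_exposure_sd, scaling_sd


@dataclass
class RescaledEffect:
    """A per-SD genetic estimate mapped onto a trial-induced exposure change."""

    scaling_sd: float
    factor_per_allele: float
    effect: float                    # rescaled point estimate (log-odds or linear)
    ci: tuple[float, float]
    exclusion_bound: float           # rescaled harm-direction CI limit
    binary_outcome: bool = True

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (np.exp(self.effect), np.exp(self.ci[0]), np.exp(self.ci[1]))


def rescale_effect(
    per_sd: WaldEstimate, scaling_sd: float, harm_direction: int = +1
) -> RescaledEffect:
    """Rescale a per-SD estimate to a trial-induced exposure change.

    The point estimate and both CI bounds scale linearly on the log-odds
    (or linear) scale, so odds ratios are raised to the power
    ``scaling_sd``. ``harm_direction`` picks which rescaled CI bound is
    quoted as the exclusion bound (+1: upper / harm = increase).
    """
    effect = per_sd.ratio * scaling_sd
    lo, hi = per_sd.ci[0] * scaling_sd, per_sd.ci[1] * scaling_sd
    if scaling_sd < 0:
        lo, hi = hi, lo
    bound = hi if harm_direction > 0 else lo
    if per_sd.binary_outcome:
        bound = float(np.exp(bound))
    factor = scaling_sd / per_sd.beta_exposure if per_sd.beta_exposure else np.nan
    return RescaledEffect(
        scaling_sd=scaling_sd, factor_per_allele=float(factor),
        effect=float(effect), ci=(float(lo), float(hi)),
        exclusion_bound=float(bound), binary_outcome=per_sd.binary_outcome,
    )


def wald_from_or(or_point: float, ci: tuple[float, float], instrument: str = "",
                 beta_exposure: float = 1.0) -> WaldEstimate:
    """Build a per-SD WaldEstimate from a published OR and 95% CI.

    Convenience for rescaling printed per-SD odds ratios; the implied SE is
    recovered from the CI width on the log scale.
    """
    ratio = float(np.log(or_point))
    lo, hi = float(np.log(ci[0])), float(np.log(ci[1]))
    se = (hi - lo) / (2.0 * Z95)
    return WaldEstimate(
        ratio=ratio, se_ratio=se, ci=(lo, hi), instrument=instrument,
        beta_exposure=beta_exposure, se_exposure=0.0,
        beta_outcome=ratio * beta_exposure, se_outcome=se * abs(beta_exposure),
    )
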