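"""Single-variant phenome-wide association scan.

One variant's dosage is tested against many traits: continuous traits are
rank-based inverse-normal transformed then fit by linear regression; binary
traits by logistic regression. Per-trait complete-case sample sizes are
recorded and rows are ordered by ascending p. Traits with fewer than two
distinct values (or failed fits) are emitted with status ``degenerate`` and
no statistics, so the output always has one row per input trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SchemaError
from .gwas import inverse_normal_transform
from .sumstats import floor_pvalues

DEFAULT_THRESHOLD = 5e-8


def _linear(dosage: np.ndarray, y: np.ndarray):
    y = inverse_normal_transform(y)
    g = dosage - dosage.mean()
    yc = y - y.mean()
    sxx = float(g @ g)
    if sxx <= 0:
        return None
    beta = float(g @ yc) / sxx
    dof = max(len(y) - 2, 1)
    sigma2 = max(float(yc @ yc) - beta**2 * sxx, 0.0) / dof
    se = np.sqrt(max(sigma2, 1e-300) / sxx)
    return beta, se


def _logistic(dosage: np.ndarray, y: np.ndarray):
    X = sm.add_constant(dosage)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return None
    if not np.all(np.isfinite(fit.bse)) or fit.bse[1] <= 0:
        return None
    return float(fit.params[1]), float(fit.bse[1])


def phewas_scan(
    dosage,
    traits: pd.DataFrame,
    trait_types: dict[str, str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Scan one variant against a trait matrix.

    Parameters
    ----------
    dosage : array of additive genotype codes, one per sample.
    traits : DataFrame, one column per trait; NaN marks missingness.
    trait_types : mapping trait -> "continuous" | "binary". Columns absent
        from the mapping (or when it is None) are treated as binary when
        their non-missing values are a subset of {0, 1}, else continuous.
    threshold : significance level for the ``significant`` flag.

    Returns one row per trait with beta, se, p, n, trait_type, status and
    significance flag, sorted by ascending p (degenerate rows last).
    """
    dosage = np.asarray(dosage, dtype=float)
    if len(dosage) != len(traits):
        raise SchemaError("dosage length does not match trait matrix rows")
    rows = []
    for name in traits.columns:
        y_full = traits[name].to_numpy(dtype=float)
        mask = np.isfinite(y_full) & np.isfinite(dosage)
        y, g = y_full[mask], dosage[mask]
        n = int(mask.sum())
        if trait_types and name in trait_types:
            ttype = trait_types[name]
        else:
            vals = np.unique(y)
            ttype = "binary" if np.all(np.isin(vals, (0.0, 1.0))) else "continuous"
        if n < 3 or len(np.unique(y)) < 2 or len(np.unique(g)) < 2:
            rows.append((name, np.nan, np.nan, np.nan, n, ttype, "degenerate"))
            continue
        res = _linear(g, y) if ttype == "continuous" else _logistic(g, y)
        if res is None:
            rows.append((name, np.nan, np.nan, np.nan, n, ttype, "degenerate"))
            continue
        beta, se = res
        p, _ = floor_pvalues(np.array([2.0 * stats.norm.sf(abs(beta / se))]))
        rows.append((name, beta, se, float(p[0]), n, ttype, "ok"))
    out = pd.DataFrame(
        rows, columns=["trait", "beta", "se", "p", "n", "trait_type", "status"]
    )
    out["significant"] = out["p"] < threshold
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def simulate_trait_matrix(
    n: int,
    n_traits: int,
    seed: int,
    frac_binary: float = 0.2,
    dosage: np.ndarray | None = None,
    effects: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Null (or partially associated) synthetic trait matrix.

    ``effects`` maps trait indices to per-allele effects (SD units for
    continuous traits, log-odds for binary); everything else is pure noise.
    Returns (trait frame, trait-type mapping).
    """
    rng = np.random.default_rng(seed)
    n_binary = int(round(frac_binary * n_traits))
    data, types = {}, {}
    for i in range(n_traits):
        name = f"trait{i:04d}"
        eff = (effects or {}).get(i, 0.0)
        lin = eff * dosage if (dosage is not None and eff) else 0.0
        if i < n_binary:
            logit = -2.0 + lin
            data[name] = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)), size=n).astype(float)
            types[name] = "binary"
        else:
            data[name] = lin + rng.standard_normal(n)
            types[name] = "continuous"
    return pd.DataFrame(data), types
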