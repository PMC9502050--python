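"""End-to-end orchestration: simulate -> cohort GWAS -> meta-analysis ->
conditional selection -> colocalization -> MR + trial rescaling -> PheWAS.

Configuration is a nested mapping (YAML on disk) that round-trips
read -> write -> read identically. All randomness flows from the config
seed; stage outputs carry no timestamps, so a rerun with the same config
produces byte-identical files. Each stage writes a provenance record
(inputs, parameters, seed, package version).
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cojo import stepwise_select
from .coloc import coloc_posteriors, restrict_window
from .errors import OrchestrationError
from .gwas import QCThresholds, association_scan, inverse_normal_transform, qc_filter
from .ld import ld_from_genotypes, write_ld
from .meta import align_alleles, ivw_meta
from .mr import (
    TrialEffect, UnitMap, combine_outcome_sources, convert_units,
    rescale_effect, scaling_factor, wald_ratio,
)
from .phewas import phewas_scan, simulate_trait_matrix
from .simulate import (
    GenotypeMatrix, SimulationConfig, simulate_cohorts, simulate_eqtl_summary,
    simulate_outcome_summary,
)
from .sumstats import write_sumstats

STAGES = ("simulate", "gwas", "meta", "cojo", "coloc", "mr", "phewas")

_REQUIRES = {
    "gwas": ("cohorts", "simulate"),
    "meta": ("cohort_stats", "gwas"),
    "cojo": ("meta_qc", "meta"),
    "coloc": ("meta_qc", "meta"),
    "mr": ("meta_qc", "meta"),
    "phewas": ("pooled", "simulate"),
}


def default_config() -> dict:
    """Emulated study design for the synthetic pipeline."""
    return {
        "seed": 0,
        "out_dir": "epomr_out",
        "stages": {s: True for s in STAGES},
        "simulation": {
            "n_per_cohort": [1210, 2954, 458, 1505],
            "n_variants": 120,
            "causal_index": 60,
            "beta_causal": 0.063,
            "maf_range": [0.05, 0.5],
            "ld_decay": 10.0,
            "skew": 0.4,
        },
        "qc": {"mac_min": 3, "info_min": 0.3, "maf_min": 0.01},
        "cojo": {"p_threshold": 5e-8, "collinearity_r2": 0.9, "window_bp": 10_000_000},
        "coloc": {
            "eqtl_n": 861, "eqtl_effect": 0.3, "shared_causal": True,
            "window_bp": 500_000, "p1": 1e-4, "p2": 1e-4, "p12": 1e-5,
            "prior_sd": [0.15, 0.15],
        },
        "mr": {
            "true_or_per_sd": 1.0,
            "outcome_sources": [
                {"name": "public", "n_cases": 60801, "n_controls": 123504},
                {"name": "biobank", "n_cases": 37741, "n_controls": 318892},
            ],
            "sd_in_natural_units": 5.1,
            "trial_median_change": 27.1,
            "trial_baseline_sd": 61.0,
            "method": "first_order",
        },
        "phewas": {"n_samples": 5000, "n_traits": 869, "frac_binary": 0.1,
                   "threshold": 5e-8},
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path) -> dict:
    """Read a YAML config, merged over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _need(state: dict, key: str, stage: str) -> None:
    if key not in state:
        produced_by = _REQUIRES[stage][1]
        raise OrchestrationError(
            f"stage '{stage}' requires output of stage '{produced_by}', "
            f"which did not run"
        )


def run_all(config: dict, out_dir=None) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the in-memory results (state dict); writes per-stage TSVs plus
    ``provenance.json`` and the resolved config under the output directory.
    """
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    seed = int(cfg["seed"])
    provenance: list[dict] = []
    state: dict = {}

    sim_cfg = SimulationConfig(
        n_per_cohort=tuple(cfg["simulation"]["n_per_cohort"]),
        n_variants=int(cfg["simulation"]["n_variants"]),
        causal_index=int(cfg["simulation"]["causal_index"]),
        beta_causal=float(cfg["simulation"]["beta_causal"]),
        maf_range=tuple(cfg["simulation"]["maf_range"]),
        ld_decay=float(cfg["simulation"]["ld_decay"]),
        skew=float(cfg["simulation"]["skew"]),
        seed=seed,
    )

    def record(stage, params, inputs):
        provenance.append(
            {"stage": stage, "inputs": inputs, "parameters": params,
             "seed": seed, "version": __version__}
        )

    if stages.get("simulate"):
        cohorts = simulate_cohorts(sim_cfg)
        pooled_dos = np.vstack([c["genotypes"].dosages for c in cohorts])
        state["cohorts"] = cohorts
        state["pooled"] = GenotypeMatrix(pooled_dos, cohorts[0]["genotypes"].panel)
        state["pooled_pheno"] = np.concatenate([c["phenotype"] for c in cohorts])
        record("simulate", cfg["simulation"], [])

    if stages.get("gwas"):
        _need(state, "cohorts", "gwas")
        thr = QCThresholds(
            mac_min=int(cfg["qc"]["mac_min"]), info_min=float(cfg["qc"]["info_min"]),
            maf_min=float(cfg["qc"]["maf_min"]),
        )
        cohort_stats, logs = [], []
        for c in state["cohorts"]:
            y = inverse_normal_transform(c["phenotype"])
            ss = association_scan(c["genotypes"], y)
            kept, log = qc_filter(ss, thr, stage="pre_meta")
            log["cohort"] = c["name"]
            cohort_stats.append(kept)
            logs.append(log)
            write_sumstats(kept, out / f"gwas_{c['name']}.tsv")
        state["cohort_stats"] = cohort_stats
        state["qc_thresholds"] = thr
        pd.concat(logs, ignore_index=True).to_csv(
            out / "qc_exclusions_pre_meta.tsv", sep="\t", index=False
        )
        record("gwas", cfg["qc"], [f"gwas_{c['name']}.tsv" for c in state["cohorts"]])

    if stages.get("meta"):
        _need(state, "cohort_stats", "meta")
        panel = state["cohorts"][0]["genotypes"].panel
        aligned = [align_alleles(s, panel)[0] for s in state["cohort_stats"]]
        meta_df = ivw_meta(aligned)
        kept, log = qc_filter(meta_df, state["qc_thresholds"], stage="post_meta")
        state["meta"] = meta_df
        state["meta_qc"] = kept
        write_sumstats(kept, out / "meta.tsv")
        log.to_csv(out / "qc_exclusions_post_meta.tsv", sep="\t", index=False)
        record("meta", {"scheme": "ivw"}, ["gwas_* tables"])

    if stages.get("cojo"):
        _need(state, "meta_qc", "cojo")
        ldm = ld_from_genotypes(state["pooled"])
        write_ld(ldm, out / "ld.txt")
        res = stepwise_select(
            state["meta_qc"], ldm,
            p_threshold=float(cfg["cojo"]["p_threshold"]),
            collinearity_r2=float(cfg["cojo"]["collinearity_r2"]),
            window_bp=float(cfg["cojo"]["window_bp"]),
        )
        state["cojo"] = res
        res.joint.to_csv(out / "cojo.tsv", sep="\t", index=False)
        with open(out / "cojo_trace.json", "w") as fh:
            json.dump(res.trace, fh, indent=1, sort_keys=True)
        record("cojo", cfg["cojo"], ["meta.tsv", "ld.txt"])

    if stages.get("coloc"):
        _need(state, "meta_qc", "coloc")
        cc = cfg["coloc"]
        eqtl = simulate_eqtl_summary(
            sim_cfg, shared_causal=bool(cc["shared_causal"]),
            effect_size=float(cc["eqtl_effect"]), n=int(cc["eqtl_n"]),
            seed=seed + 7700,
        )
        center = int(state["pooled"].panel["POS"].iloc[sim_cfg.causal_index])
        t1 = restrict_window(state["meta_qc"], center, int(cc["window_bp"]))
        t2 = restrict_window(eqtl, center, int(cc["window_bp"]))
        res = coloc_posteriors(
            t1, t2, priors=(float(cc["p1"]), float(cc["p2"]), float(cc["p12"])),
            prior_sd=tuple(float(x) for x in cc["prior_sd"]),
        )
        state["coloc"] = res
        state["eqtl"] = eqtl
        res.to_frame().to_csv(out / "coloc.tsv", sep="\t", index=False)
        res.abf_frame().to_csv(out / "coloc_abf.tsv", sep="\t", index=False)
        record("coloc", cc, ["meta.tsv", "eqtl (simulated)"])

    if stages.get("mr"):
        _need(state, "meta_qc", "mr")
        mc = cfg["mr"]
        instrument = state["pooled"].panel["SNP"].iloc[sim_cfg.causal_index]
        exp_row = state["meta_qc"].set_index("SNP").loc[instrument]
        panel = state["pooled"].panel
        sources = []
        for i, src in enumerate(mc["outcome_sources"]):
            ss = simulate_outcome_summary(
                panel, float(mc["true_or_per_sd"]), float(exp_row["BETA"]),
                sim_cfg.causal_index, int(src["n_cases"]), int(src["n_controls"]),
                seed=seed + 3100 + i,
            )
            row = ss.set_index("SNP").loc[instrument]
            sources.append({"beta": float(row["BETA"]), "se": float(row["SE"]),
                            "n": int(row["N"])})
        pooled_out = sources[0]
        for s in sources[1:]:
            pooled_out = combine_outcome_sources(pooled_out, s)
        wald = wald_ratio(
            float(exp_row["BETA"]), float(exp_row["SE"]),
            pooled_out["beta"], pooled_out["se"],
            method=mc["method"], instrument=instrument,
        )
        trial = TrialEffect(float(mc["trial_median_change"]),
                            float(mc["trial_baseline_sd"]))
        factor, scaling_sd = scaling_factor(trial, float(exp_row["BETA"]))
        rescaled = rescale_effect(wald, scaling_sd)
        umap = UnitMap(float(mc["sd_in_natural_units"]))
        state["mr"] = {
            "wald": wald, "rescaled": rescaled, "factor": factor,
            "scaling_sd": scaling_sd,
            "beta_exposure_iu": convert_units(float(exp_row["BETA"]), umap),
            "trial_change_iu": convert_units(scaling_sd, umap),
        }
        or_, lo, hi = wald.or_scale
        ror, rlo, rhi = rescaled.or_scale
        report = pd.DataFrame(
            [{
                "instrument": instrument, "or_per_sd": or_, "ci_low": lo,
                "ci_high": hi, "p": wald.p, "scaling_sd": scaling_sd,
                "factor_per_allele": factor, "rescaled_or": ror,
                "rescaled_ci_low": rlo, "rescaled_ci_high": rhi,
                "exclusion_bound": rescaled.exclusion_bound,
            }]
        )
        report.to_csv(out / "mr.tsv", sep="\t", index=False)
        with open(out / "mr_summary.txt", "w") as fh:
            fh.write(
                f"Instrument {instrument}: OR per exposure SD = {or_:.3f} "
                f"[{lo:.3f}, {hi:.3f}], p = {wald.p:.3g}\n"
                f"Trial-induced exposure change = {scaling_sd:.3f} SD "
                f"({state['mr']['trial_change_iu']:.2f} IU/L); "
                f"per-allele factor = {factor:.2f}\n"
                f"Rescaled OR = {ror:.3f} [{rlo:.3f}, {rhi:.3f}]; "
                f"can exclude OR > {rescaled.exclusion_bound:.3f}\n"
            )
        record("mr", mc, ["meta.tsv", "outcome (simulated)"])

    if stages.get("phewas"):
        _need(state, "pooled", "phewas")
        pc = cfg["phewas"]
        n = int(pc["n_samples"])
        from .simulate import simulate_genotypes
        gt = simulate_genotypes(sim_cfg, n_samples=n, seed=seed + 9100)
        dosage = gt.dosages[:, sim_cfg.causal_index].astype(float)
        traits, types = simulate_trait_matrix(
            n, int(pc["n_traits"]), seed=seed + 9200,
            frac_binary=float(pc["frac_binary"]), dosage=dosage,
        )
        table = phewas_scan(dosage, traits, types,
                            threshold=float(pc["threshold"]))
        state["phewas"] = table
        table.to_csv(out / "phewas.tsv", sep="\t", index=False)
        record("phewas", pc, ["dosage (simulated)", "traits (simulated)"])

    save_config(cfg, out / "config_used.yaml")
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return state
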