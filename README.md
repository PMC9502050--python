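# epomr

Drug-target Mendelian randomization (MR) toolkit for a circulating protein
biomarker, built around the cis-EPO use case: does genetically predicted,
long-term elevation of endogenous erythropoietin (EPO) — a proxy for
EPO-raising therapies such as HIF prolyl-hydroxylase inhibitors — increase
cardiovascular risk?

The package implements the full statistical chain as a reusable library:

1. **Cohort GWAS** — rank-based inverse-normal transform of a skewed
   biomarker (Blom offset 3/8), additive association scan, MAC/EAF/Info and
   MAF variant QC;
2. **Meta-analysis** — allele alignment and METAL-style inverse-variance-
   weighted fixed-effects pooling (`β̂ = Σwβ/Σw`, `w = 1/SE²`), plus a
   sample-size-weighted z-score scheme for eQTL-style inputs;
3. **Conditional selection** — GCTA-COJO-style stepwise conditional and
   joint analysis from summary statistics and an LD reference, using
   `D½RD½` as the X'X surrogate (`D_j = 2f_j(1−f_j)n_j`, or exact sample
   variances when LD comes from genotypes);
4. **Colocalization** — Wakefield approximate Bayes factors
   (`log ABF = ½log(1−r) + z²r/2`, `r = W/(V+W)`) and posterior
   probabilities PP0–PP4 for shared vs distinct causal variants between the
   biomarker association and a regional eQTL signal;
5. **Wald-ratio MR** — single cis instrument, `β_out/β_exp` with
   delta-method SE, outcome sources IVW-pooled first;
6. **Trial rescaling** — mapping per-SD genetic estimates onto a
   clinical-trial-induced exposure change (`scaling_sd =
   median_change/baseline_SD`; odds ratios raised to the power
   `scaling_sd`), with harm-direction exclusion bounds;
7. **PheWAS** — one variant against many traits (linear for inverse-
   normalised continuous traits, logistic for binary).

Because the original cohort, outcome-consortium and biobank data are
restricted, a first-class **synthetic-data module** generates multi-cohort
genotypes (Hardy–Weinberg dosages with AR(1)-style decaying LD), a
right-skewed biomarker driven by one cis causal variant (default: four
cohorts of 1,210/2,954/458/1,505 samples, effect 0.063 SD per allele),
mediation-consistent binary-outcome summary statistics, and regional eQTL
summary statistics with a shared or distinct causal variant. Every stage of
the chain is validated against independent oracles (hand arithmetic,
brute-force enumeration, individual-level regression) and calibration
simulations. See `docs/methods.md` for the model details and design
choices.

## Worked example

Run the full synthetic pipeline at the default (emulated study design) scale:

```python
from epomr.pipeline import default_config, run_all

cfg = default_config()
cfg["seed"] = 1
state = run_all(cfg, out_dir="demo_out")
```

or equivalently `epomr run --seed 1 --out demo_out` from the shell. The
biomarker meta-analysis row for the causal variant (`demo_out/meta.tsv`):

```
beta 0.0807  se 0.0237  p 0.000667  n 6127
```

— the per-allele effect recovered at pooled n = 6,127, consistent with the
planted 0.063 SD (the estimate sits on the inverse-normalised scale; a cis
effect of this size is nowhere near genome-wide significance, which is why
the conditional-selection stage correctly selects nothing at 5×10⁻⁸ and
the variant is used as a *cis* instrument instead). Colocalization of the
biomarker signal with the simulated shared-causal liver eQTL (n = 861,
effect 0.3) gives `PP4 = 0.786` — at this biomarker signal strength
(z ≈ 3), shared-causal evidence is genuinely moderate, not decisive. The
MR report (`demo_out/mr_summary.txt`, outcome simulated under a true null
OR of 1.0):

```
Instrument rs900060: OR per exposure SD = 0.997 [0.917, 1.083], p = 0.941
Trial-induced exposure change = 0.444 SD (2.27 IU/L); per-allele factor = 5.51
Rescaled OR = 0.999 [0.962, 1.036]; can exclude OR > 1.036
```

Reading it: one exposure-SD higher biomarker shows no outcome association;
rescaled to the trial-induced exposure change (0.44 SD), the odds ratio is
0.999, and the upper confidence bound lets the analysis exclude adverse
odds above 1.036 for a trial-sized exposure increase. The PheWAS stage
scans 869 synthetic null traits and flags none at 5×10⁻⁸.

The rescaling arithmetic itself is exposed directly:

```python
from epomr.mr import TrialEffect, UnitMap, scaling_factor, convert_units

factor, scaling_sd = scaling_factor(TrialEffect(27.1, 61.0), 0.063)
# factor = 7.05, scaling_sd = 0.44
convert_units(0.063, UnitMap(5.1))   # 0.32 IU/L per allele
```

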