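"""Synthetic-data generator: determinism, HWE, LD decay, noise shape."""

import numpy as np
import pytest
from scipy import stats

from epomr.errors import ConfigurationError
from epomr.simulate import (
    SimulationConfig, TrialEffect, lognormal_skewness, simulate_biomarker,
    simulate_cohorts, simulate_eqtl_summary, simulate_genotypes,
    simulate_outcome_summary, skewed_noise,
)


def test_identical_seed_gives_byte_identical_outputs():
    cfg = SimulationConfig(n_per_cohort=(500,), n_variants=20, causal_index=10, seed=5)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    assert a.dosages.tobytes() == b.dosages.tobytes()
    ya = simulate_biomarker(a, cfg)
    yb = simulate_biomarker(b, cfg)
    assert ya.tobytes() == yb.tobytes()


def test_different_seeds_differ():
    cfg1 = SimulationConfig(n_per_cohort=(500,), n_variants=10, causal_index=5, seed=1)
    cfg2 = SimulationConfig(n_per_cohort=(500,), n_variants=10, causal_index=5, seed=2)
    assert not np.array_equal(simulate_genotypes(cfg1).dosages,
                              simulate_genotypes(cfg2).dosages)


def test_dosages_are_additive_codes_and_polymorphic():
    cfg = SimulationConfig(n_per_cohort=(300,), n_variants=25, causal_index=0,
                           maf_range=(0.05, 0.5), seed=3)
    gt = simulate_genotypes(cfg)
    assert set(np.unique(gt.dosages)) <= {0, 1, 2}
    f = gt.sample_freqs()
    assert np.all((f > 0) & (f < 1))


def test_sample_frequency_concentrates_at_half():
    # maf_range (0.5, 0.5): binomial(2n, 0.5) concentration at n = 50,000
    cfg = SimulationConfig(n_per_cohort=(50000,), n_variants=1, causal_index=0,
                           maf_range=(0.5, 0.5), seed=9)
    f = simulate_genotypes(cfg).sample_freqs()[0]
    lo, hi = stats.binom.interval(0.9999, 2 * 50000, 0.5)
    assert lo / 100000 <= f <= hi / 100000
    assert 0.49 <= f <= 0.51


def test_frequency_conservation_matches_panel():
    cfg = SimulationConfig(n_per_cohort=(20000,), n_variants=15, causal_index=0,
                           seed=21)
    gt = simulate_genotypes(cfg)
    f_pop = gt.panel["FREQ_A1"].to_numpy()
    f_hat = gt.sample_freqs()
    # 2n draws per variant -> binomial SE
    se = np.sqrt(f_pop * (1 - f_pop) / (2 * 20000))
    assert np.all(np.abs(f_hat - f_pop) < 5 * se)


def test_tiny_ld_decay_gives_independent_variants():
    cfg = SimulationConfig(n_per_cohort=(50000,), n_variants=6, causal_index=0,
                           ld_decay=1e-6, seed=13)
    gt = simulate_genotypes(cfg)
    r = np.corrcoef(gt.dosages.T.astype(float))
    off = r[~np.eye(6, dtype=bool)]
    assert np.all(np.abs(off) < 0.05)


def test_ld_decays_with_index_distance():
    cfg = SimulationConfig(n_per_cohort=(20000,), n_variants=40, causal_index=0,
                           ld_decay=10.0, seed=17)
    gt = simulate_genotypes(cfg)
    r = np.corrcoef(gt.dosages.T.astype(float))
    near = np.mean([abs(r[i, i + 1]) for i in range(39)])
    far = np.mean([abs(r[i, i + 30]) for i in range(10)])
    assert near > 0.4 > far


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_per_cohort=(0,), n_variants=5, causal_index=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        SimulationConfig(ld_decay=0.0)
    with pytest.raises(IndexError):
        SimulationConfig(n_variants=5, causal_index=5)
    with pytest.raises(ConfigurationError):
        TrialEffect(median_change=1.0, baseline_sd=0.0)


class TestBiomarker:
    def test_null_effect_gives_no_association(self):
        cfg = SimulationConfig(n_per_cohort=(5000,), n_variants=5, causal_index=2,
                               beta_causal=0.0, seed=23)
        gt = simulate_genotypes(cfg)
        y = simulate_biomarker(gt, cfg)
        g = gt.dosages[:, 2].astype(float)
        res = stats.linregress(g, y)
        assert abs(res.slope) < 2.5 * res.stderr

    def test_effect_recovered_at_large_n(self):
        # planted 0.063 SD per allele; OLS at n = 100,000
        cfg = SimulationConfig(n_per_cohort=(100000,), n_variants=3, causal_index=1,
                               beta_causal=0.063, seed=29)
        gt = simulate_genotypes(cfg)
        y = simulate_biomarker(gt, cfg)
        slope = stats.linregress(gt.dosages[:, 1].astype(float), y).slope
        assert 0.053 <= slope <= 0.073

    def test_noise_skewness_matches_closed_form(self):
        rng = np.random.default_rng(31)
        x = skewed_noise(rng, 200000, 0.4)
        assert abs(float(np.mean(x))) < 0.02
        assert abs(float(np.var(x)) - 1.0) < 0.05
        expected = lognormal_skewness(0.4)
        assert expected > 0
        assert abs(stats.skew(x) - expected) < 0.25 * expected

    def test_positive_skew_in_phenotype(self):
        cfg = SimulationConfig(n_per_cohort=(10000,), n_variants=3, causal_index=0,
                               skew=0.4, seed=37)
        gt = simulate_genotypes(cfg)
        y = simulate_biomarker(gt, cfg)
        assert stats.skew(y) > 0.5


class TestOutcomeSummary:
    def test_null_or_gives_zero_mean_beta(self):
        cfg = SimulationConfig(n_per_cohort=(100,), n_variants=4, causal_index=1,
                               seed=43)
        panel = simulate_genotypes(cfg).panel
        betas = [
            simulate_outcome_summary(panel, 1.0, 0.063, 1, 50000, 50000, seed=s)
            .loc[1, "BETA"]
            for s in range(500)
        ]
        se = simulate_outcome_summary(panel, 1.0, 0.063, 1, 50000, 50000, seed=0).loc[
            1, "SE"
        ]
        assert abs(np.mean(betas)) < 2 * se / np.sqrt(500)

    def test_expected_log_or_closed_form(self):
        # ln(1.5) * 0.063 = 0.025547
        cfg = SimulationConfig(n_per_cohort=(100,), n_variants=4, causal_index=1,
                               seed=47)
        panel = simulate_genotypes(cfg).panel
        betas = [
            simulate_outcome_summary(panel, 1.5, 0.063, 1, 200000, 200000, seed=s)
            .loc[1, "BETA"]
            for s in range(400)
        ]
        assert abs(np.mean(betas) - np.log(1.5) * 0.063) < 3e-4

    def test_se_follows_binary_trait_approximation(self):
        cfg = SimulationConfig(n_per_cohort=(100,), n_variants=3, causal_index=0,
                               seed=53)
        panel = simulate_genotypes(cfg).panel
        ss = simulate_outcome_summary(panel, 1.0, 0.0, 0, 60801, 123504, seed=1)
        f = panel["FREQ_A1"].to_numpy()
        n_eff = 4.0 / (1 / 60801 + 1 / 123504)
        np.testing.assert_allclose(
            ss["SE"], 1.0 / np.sqrt(2 * f * (1 - f) * n_eff), rtol=1e-12
        )

    def test_invalid_counts_rejected(self):
        cfg = SimulationConfig(n_per_cohort=(100,), n_variants=3, causal_index=0,
                               seed=3)
        panel = simulate_genotypes(cfg).panel
        with pytest.raises(ConfigurationError):
            simulate_outcome_summary(panel, 1.0, 0.1, 0, 0, 100, seed=1)
        with pytest.raises(ConfigurationError):
            simulate_outcome_summary(panel, -1.0, 0.1, 0, 100, 100, seed=1)


def test_cohort_sizes_and_shared_panel():
    cfg = SimulationConfig(n_per_cohort=(121, 295, 46, 150), n_variants=12,
                           causal_index=6, seed=59)
    cohorts = simulate_cohorts(cfg)
    assert [c["genotypes"].n_samples for c in cohorts] == [121, 295, 46, 150]
    assert len(cohorts[0]["phenotype"]) == 121
    p0 = cohorts[0]["genotypes"].panel
    for c in cohorts[1:]:
        assert c["genotypes"].panel.equals(p0)


def test_eqtl_summary_peaks_at_configured_causal():
    cfg = SimulationConfig(n_per_cohort=(861,), n_variants=30, causal_index=15,
                           seed=61)
    shared = simulate_eqtl_summary(cfg, shared_causal=True, effect_size=0.5, n=861)
    assert shared["P"].idxmin() in range(10, 21)  # at or in LD with index 15
    distinct = simulate_eqtl_summary(cfg, shared_causal=False, effect_size=0.5,
                                     n=861, distinct_index=2)
    assert distinct["P"].idxmin() in range(0, 8)
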