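"""Conditional/joint selection from summary statistics + LD reference.

Primary oracle: with LD computed from the same individuals as the summary
statistics, the summary-based joint fit must reproduce individual-level
multiple regression.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epomr.cojo import conditional_stats, joint_fit, stepwise_select
from epomr.errors import CollinearityError
from epomr.gwas import association_scan
from epomr.ld import LDMatrix, ld_from_genotypes
from epomr.simulate import SimulationConfig, simulate_genotypes


def _orthogonal_ld(snps, freqs, n):
    m = len(snps)
    return LDMatrix(
        variant_ids=list(snps), r=np.eye(m), freqs=np.asarray(freqs), n_ref=n,
        pos=np.arange(m, dtype=float),
    )


def _marginal(snps, betas, ses, freqs, n):
    betas, ses = np.asarray(betas, float), np.asarray(ses, float)
    return pd.DataFrame(
        {
            "SNP": snps,
            "CHR": "7",
            "POS": np.arange(len(snps)) + 1,
            "A1": "A",
            "A2": "G",
            "FREQ_A1": freqs,
            "BETA": betas,
            "SE": ses,
            "P": 2 * stats.norm.sf(np.abs(betas / ses)),
            "N": n,
            "INFO": 1.0,
        }
    )


def _two_causal_sim(seed, n=10000, m=60, b=0.15, idx=(20, 36)):
    cfg = SimulationConfig(n_per_cohort=(n,), n_variants=m, causal_index=idx[0],
                           beta_causal=b, maf_range=(0.25, 0.5), skew=0.0,
                           seed=seed)
    gt = simulate_genotypes(cfg)
    rng = np.random.default_rng([seed, 99])
    y = (
        b * gt.dosages[:, idx[0]].astype(float)
        + b * gt.dosages[:, idx[1]].astype(float)
        + rng.standard_normal(n)
    )
    return gt, y, association_scan(gt, y), ld_from_genotypes(gt)


class TestConditionalStats:
    def test_orthogonal_panel_conditional_equals_marginal(self):
        snps = ["a", "b", "c", "d"]
        marg = _marginal(snps, [0.2, 0.1, -0.05, 0.3], [0.02, 0.03, 0.04, 0.05],
                         0.4, 5000)
        ld = _orthogonal_ld(snps, [0.4] * 4, 5000)
        cond, log = conditional_stats(marg, ["a"], ld)
        cond = cond.set_index("SNP")
        for s in ("b", "c", "d"):
            row = marg.set_index("SNP").loc[s]
            assert cond.loc[s, "COND_BETA"] == pytest.approx(row["BETA"], abs=1e-10)
            assert cond.loc[s, "COND_SE"] == pytest.approx(row["SE"], abs=1e-10)
        assert len(log) == 0

    def test_perfect_ld_candidate_excluded(self):
        snps = ["a", "b"]
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LDMatrix(snps, r, freqs=np.array([0.4, 0.4]), n_ref=1000,
                      pos=np.array([1.0, 2.0]))
        marg = _marginal(snps, [0.2, 0.2], [0.02, 0.02], 0.4, 1000)
        cond, log = conditional_stats(marg, ["a"], ld)
        assert "b" not in set(cond["SNP"])
        assert list(log["snp_id"]) == ["b"]

    def test_conditional_matches_individual_level_regression(self):
        gt, y, marg, ld = _two_causal_sim(907)
        sel = [gt.panel["SNP"].iloc[20]]
        cond = conditional_stats(marg, sel, ld)[0].set_index("SNP")
        # oracle: per-candidate two-covariate OLS on the individual data
        for j in (25, 36, 45):
            X = np.column_stack(
                [np.ones(len(y)), gt.dosages[:, 20], gt.dosages[:, j]]
            ).astype(float)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            snp = gt.panel["SNP"].iloc[j]
            resid = y - X @ coef
            sig2 = resid @ resid / (len(y) - 3)
            se = np.sqrt(sig2 * np.linalg.inv(X.T @ X)[2, 2])
            assert cond.loc[snp, "COND_BETA"] == pytest.approx(coef[2], abs=2 * se)


class TestJointFit:
    def test_singleton_equals_marginal(self):
        snps = ["a", "b"]
        marg = _marginal(snps, [0.2, 0.05], [0.02, 0.03], 0.4, 5000)
        ld = _orthogonal_ld(snps, [0.4, 0.4], 5000)
        joint = joint_fit(marg, ["a"], ld)
        assert joint.loc[0, "JOINT_BETA"] == pytest.approx(0.2, abs=1e-12)
        assert joint.loc[0, "JOINT_SE"] == pytest.approx(0.02, abs=1e-10)

    def test_orthogonal_pair_keeps_marginal_betas(self):
        snps = ["a", "b"]
        marg = _marginal(snps, [0.2, 0.1], [0.02, 0.02], 0.4, 5000)
        joint = joint_fit(marg, ["a", "b"], _orthogonal_ld(snps, [0.4, 0.4], 5000))
        np.testing.assert_allclose(joint["JOINT_BETA"], [0.2, 0.1], atol=1e-12)

    def test_exact_ld_reproduces_multiple_regression(self):
        gt, y, marg, ld = _two_causal_sim(911)
        sel = [gt.panel["SNP"].iloc[20], gt.panel["SNP"].iloc[36]]
        joint = joint_fit(marg, sel, ld)
        X = np.column_stack(
            [np.ones(len(y)), gt.dosages[:, 20], gt.dosages[:, 36]]
        ).astype(float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(
            joint["JOINT_BETA"].to_numpy(), coef[1:], rtol=1e-6
        )

    def test_singular_selected_set_names_pair(self):
        snps = ["a", "b"]
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LDMatrix(snps, r, freqs=np.array([0.4, 0.4]), n_ref=1000,
                      pos=np.array([1.0, 2.0]))
        marg = _marginal(snps, [0.2, 0.2], [0.02, 0.02], 0.4, 1000)
        with pytest.raises(CollinearityError, match="a / b|b / a"):
            joint_fit(marg, ["a", "b"], ld)


class TestStepwiseSelect:
    def test_no_significant_variants_empty_selection(self):
        snps = ["a", "b", "c"]
        marg = _marginal(snps, [0.01, 0.02, -0.01], [0.02, 0.03, 0.02], 0.4, 5000)
        res = stepwise_select(marg, _orthogonal_ld(snps, [0.4] * 3, 5000))
        assert res.selected == []
        assert len(res.joint) == 0

    def test_single_causal_orthogonal_panel(self):
        snps = ["a", "b", "c"]
        marg = _marginal(snps, [0.2, 0.01, -0.01], [0.02, 0.02, 0.02], 0.4, 5000)
        res = stepwise_select(marg, _orthogonal_ld(snps, [0.4] * 3, 5000))
        assert res.selected == ["a"]
        assert res.joint.loc[0, "JOINT_BETA"] == pytest.approx(0.2, abs=1e-12)

    def test_two_planted_signals_recovered_across_seeds(self):
        hits, exact = 0, 0
        for seed in range(20):
            gt, y, marg, ld = _two_causal_sim(1000 + seed)
            res = stepwise_select(marg, ld)
            truth = {gt.panel["SNP"].iloc[20], gt.panel["SNP"].iloc[36]}
            if set(res.selected) == truth:
                exact += 1
                joint = res.joint.set_index("SNP")
                ok = all(
                    abs(joint.loc[s, "JOINT_BETA"] - 0.15)
                    < 2 * joint.loc[s, "JOINT_SE"]
                    for s in truth
                )
                hits += ok
        assert exact == 20
        assert hits >= 18

    def test_selection_invariant_to_input_order(self):
        gt, y, marg, ld = _two_causal_sim(977)
        shuffled = marg.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = stepwise_select(marg, ld)
        b = stepwise_select(shuffled, ld)
        assert set(a.selected) == set(b.selected)

    def test_looser_threshold_superset_of_stricter(self):
        gt, y, marg, ld = _two_causal_sim(941)
        loose = stepwise_select(marg, ld, p_threshold=5e-8)
        strict = stepwise_select(marg, ld, p_threshold=5e-12)
        assert set(strict.selected) <= set(loose.selected)

    def test_joint_p_below_threshold_at_exit(self):
        gt, y, marg, ld = _two_causal_sim(953)
        res = stepwise_select(marg, ld)
        assert len(res.selected) > 0
        assert (res.joint["JOINT_P"] < res.p_threshold).all()
        # pairwise reference r2 among selected below the collinearity cutoff
        idx = ld.index_of(res.selected)
        sub = ld.r[np.ix_(idx, idx)] ** 2
        np.fill_diagonal(sub, 0.0)
        assert sub.max() < 0.9
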