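import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methyldrift.differential import (
    ModelSpec,
    bh_fdr,
    build_design_matrix,
    classify_cpgs,
    compute_delta_beta,
    drop_aliased_columns,
    fit_cpg_lmm,
    fit_lmm,
    gene_locus_summary,
    run_differential,
)
from methyldrift.types import BetaMatrix, PairedDesign, SampleSheet, SubjectPair

from conftest import treated_design


def brute_force_bh(p):
    """Independent step-up implementation used as the FDR oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestDeltaBeta:
    def test_two_pair_example(self):
        beta = BetaMatrix(pd.DataFrame(
            {"a_p": [0.2], "a_f": [0.5], "b_p": [0.4], "b_f": [0.7]},
            index=["cg1"]))
        design = PairedDesign((SubjectPair("a", "a_p", "a_f"),
                               SubjectPair("b", "b_p", "b_f")))
        assert compute_delta_beta(beta, design)["cg1"] == pytest.approx(0.3)

    def test_identical_matrices_give_zero(self, small_beta, paired_design):
        delta = compute_delta_beta(small_beta, paired_design)
        same = BetaMatrix(small_beta.values.copy())
        for pair in paired_design:
            same.values[pair.followup_sample_id] = same.values[pair.primary_sample_id]
        assert (compute_delta_beta(same, paired_design) == 0).all()
        assert len(delta) == small_beta.shape[0]

    def test_missing_followup_uses_remaining_pairs(self):
        vals = pd.DataFrame(
            {"a_p": [0.1], "a_f": [np.nan], "b_p": [0.2], "b_f": [0.4],
             "c_p": [0.3], "c_f": [0.9]}, index=["cg1"])
        design = PairedDesign((SubjectPair("a", "a_p", "a_f"),
                               SubjectPair("b", "b_p", "b_f"),
                               SubjectPair("c", "c_p", "c_f")))
        delta = compute_delta_beta(BetaMatrix(vals), design)
        assert delta["cg1"] == pytest.approx((0.2 + 0.6) / 2)

    def test_empty_design_is_error(self, small_beta):
        with pytest.raises(ValueError, match="empty"):
            compute_delta_beta(small_beta, PairedDesign(()))


class TestMixedModel:
    def _paired_data(self, rng, n_subjects, effect=0.1, subj_sd=0.3, noise_sd=0.05):
        subj = np.repeat(np.arange(n_subjects), 2)
        tp = np.tile([0.0, 1.0], n_subjects)
        u = rng.normal(0, subj_sd, n_subjects)
        y = 0.5 + effect * tp + u[subj] + rng.normal(0, noise_sd, 2 * n_subjects)
        X = np.column_stack([np.ones(2 * n_subjects), tp])
        return y, X, subj

    def test_coefficient_equals_mean_delta_in_paired_design(self):
        rng = np.random.default_rng(3)
        y, X, subj = self._paired_data(rng, 6)
        fit = fit_lmm(y, X, subj, ["intercept", "timepoint"])
        mean_diff = np.mean(y[1::2] - y[0::2])
        assert fit.coefficients["timepoint"] == pytest.approx(mean_diff, abs=1e-10)

    def test_p_matches_paired_t_test(self):
        rng = np.random.default_rng(4)
        worst = 0.0
        for _ in range(25):
            n = int(rng.integers(4, 12))
            y, X, subj = self._paired_data(rng, n)
            fit = fit_lmm(y, X, subj, ["intercept", "timepoint"])
            t_p = stats.ttest_rel(y[1::2], y[0::2]).pvalue
            worst = max(worst, abs(fit.p_values["timepoint"] - t_p))
        assert worst <= 1e-6

    def test_zero_variance_ratio_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        y, X, subj = self._paired_data(rng, 8)
        fit = fit_lmm(y, X, subj, ["intercept", "timepoint"], lambda_override=0.0)
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (len(y) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert fit.coefficients["timepoint"] == pytest.approx(coef[1], abs=1e-10)
        assert fit.se["timepoint"] == pytest.approx(se, abs=1e-10)

    def test_matches_statsmodels_mixedlm_with_covariates(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n = 10
        subj = np.repeat(np.arange(n), 2)
        tp = np.tile([0.0, 1.0], n)
        age = np.repeat(rng.uniform(40, 80, n), 2)
        u = rng.normal(0, 0.3, n)
        y = 0.3 + 0.15 * tp + 0.002 * age + u[subj] + rng.normal(0, 0.05, 2 * n)
        X = np.column_stack([np.ones(2 * n), tp, age])
        fit = fit_lmm(y, X, subj, ["intercept", "timepoint", "age"])
        md = sm.MixedLM(y, X, groups=subj).fit(reml=True)
        assert fit.coefficients["timepoint"] == pytest.approx(md.params[1], abs=1e-6)
        assert fit.se["timepoint"] == pytest.approx(md.bse[1], rel=1e-3)

    def test_aliased_columns_dropped_deterministically(self):
        n = 12
        x1 = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x1, 2 * x1, x1 + 1])
        kept, names, dropped = drop_aliased_columns(
            X, ["intercept", "a", "a_twice", "a_shift"])
        assert names == ["intercept", "a"]
        assert dropped == ["a_twice", "a_shift"]

    def test_all_missing_is_error(self, paired_sheet):
        row = pd.Series(np.nan, index=paired_sheet.sample_ids)
        with pytest.raises(ValueError, match="missing"):
            fit_cpg_lmm(row, paired_sheet, ModelSpec(()))


class TestBH:
    def test_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_nan_passthrough_and_bounds(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])
        with pytest.raises(ValueError):
            bh_fdr([1.1])


class TestClassification:
    @pytest.mark.parametrize("delta,q,mode,expected", [
        (0.25, 0.01, "fdr_and_delta", "hyper"),
        (0.25, 0.2, "fdr_and_delta", "unchanged"),
        (0.25, 0.2, "delta_only", "hyper"),
        (0.20, 0.01, "fdr_and_delta", "unchanged"),  # strict >
        (-0.21, 0.01, "fdr_and_delta", "hypo"),
        (-0.20, 0.01, "delta_only", "unchanged"),
    ])
    def test_rules(self, delta, q, mode, expected):
        df = pd.DataFrame({"delta_beta": [delta], "q_value": [q]}, index=["cg1"])
        direction, counts = classify_cpgs(df, mode=mode)
        assert direction["cg1"] == expected
        assert sum(counts.values()) == 1

    def test_unknown_mode(self):
        df = pd.DataFrame({"delta_beta": [0.3], "q_value": [0.01]})
        with pytest.raises(ValueError, match="mode"):
            classify_cpgs(df, mode="bogus")


class TestRecovery:
    def test_noise_free_delta_only_recovers_exactly(self, noise_free_cohort):
        """Injected |drift| = 0.3 > 0.2 must be recovered with precision=recall=1."""
        c = noise_free_cohort
        from methyldrift.qc import run_qc
        cleaned, report = run_qc(c["beta"], c["intensities"].detection_p,
                                 c["manifest"], c["sheet"])
        design = treated_design(c)
        results = run_differential(cleaned, c["sheet"], design,
                                   spec=ModelSpec(()), mode="delta_only",
                                   fit_models=False)
        called = set(results.index[results["direction"] != "unchanged"])
        injected = set(c["truth"].drifted.index[c["truth"].drifted])
        assert called == injected

    def test_noisy_recovery_recall_and_fdr(self, noisy_cohort):
        """6 pairs, noise SD 0.05, |drift| 0.3: recall >= 0.9, FDR <= 0.1."""
        c = noisy_cohort
        from methyldrift.qc import run_qc
        cleaned, report = run_qc(c["beta"], c["intensities"].detection_p,
                                 c["manifest"], c["sheet"])
        design = treated_design(c)
        results = run_differential(cleaned, c["sheet"], design,
                                   spec=ModelSpec(()), mode="fdr_and_delta")
        called = set(results.index[results["direction"] != "unchanged"])
        injected = set(c["truth"].drifted.index[c["truth"].drifted])
        recall = len(called & injected) / len(injected)
        assert recall >= 0.9
        false_calls = len(called - injected)
        if called:
            assert false_calls / len(called) <= 0.1


class TestGeneLocusSummary:
    def test_per_cpg_table_and_flags(self, tiny_manifest):
        probes = ["cg00", "cg01", "cg04"]  # the three MGMT CpGs
        vals = pd.DataFrame(
            {"a_p": [0.1, 0.2, 0.3], "a_f": [0.4, 0.1, 0.3]},
            index=pd.Index(probes, name="probe_id"))
        design = PairedDesign((SubjectPair("a", "a_p", "a_f"),))
        per_subject, per_cpg = gene_locus_summary(
            BetaMatrix(vals), design, tiny_manifest, "MGMT")
        assert len(per_cpg) == 3
        # mean delta = (0.3 - 0.1 + 0.0)/3
        assert per_subject.at["a", "mean_delta_beta"] == pytest.approx(0.2 / 3)
        assert bool(per_subject.at["a", "increased_methylation"])

    def test_zero_change_flag_false(self, tiny_manifest):
        vals = pd.DataFrame({"a_p": [0.5], "a_f": [0.5]},
                            index=pd.Index(["cg00"], name="probe_id"))
        design = PairedDesign((SubjectPair("a", "a_p", "a_f"),))
        per_subject, _ = gene_locus_summary(BetaMatrix(vals), design,
                                            tiny_manifest, "MGMT")
        assert not bool(per_subject.at["a", "increased_methylation"])

    def test_unknown_gene_lists_alternatives(self, tiny_manifest, small_beta,
                                             paired_design):
        with pytest.raises(ValueError, match="nearest"):
            gene_locus_summary(small_beta, paired_design, tiny_manifest, "MGMTX")
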