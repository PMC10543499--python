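"""Association models, IVW fixed-effects pooling, heterogeneity, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import insuclust as ic
from insuclust.assoc import AssociationResult, meta_table


def res(beta, se, cluster="c1", outcome="T2D", cohort="co", **kw):
    return AssociationResult(
        cohort=cohort, cluster=cluster, outcome=outcome, stratum="all",
        estimate=beta, se=se, p=0.05, n=1000, n_cases=100,
        model="logistic", exposure="continuous_per10", **kw,
    )


def simulate_simple_cohort(n, beta_per10, seed, prevalence=0.2):
    """Minimal cohort + scores with a known per-10-unit effect."""
    rng = np.random.default_rng(seed)
    score = rng.normal(50.0, 10.0, size=n)
    age = rng.normal(60, 8, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    pcs = rng.normal(size=(n, 10))
    eta = beta_per10 / 10.0 * score
    alpha = np.log(prevalence / (1 - prevalence)) - eta.mean()
    y = rng.binomial(1, expit(alpha + eta))
    ids = [f"I{i}" for i in range(n)]
    cohort = pd.DataFrame({"individual_id": ids, "T2D": y, "age": age, "sex": sex})
    for j in range(10):
        cohort[f"PC{j + 1}"] = pcs[:, j]
    scores = ic.PPSTable(scores=pd.DataFrame({"c1": score}, index=ids))
    return cohort, scores


class TestFitOutcomeModel:
    def test_recovers_planted_effect(self):
        cohort, scores = simulate_simple_cohort(20000, beta_per10=0.3, seed=7)
        result = ic.fit_outcome_model(cohort, scores, "c1", "T2D")
        assert result.usable and result.model == "logistic"
        assert result.estimate == pytest.approx(0.3, abs=3 * result.se)

    def test_per10_scaling_is_linear_reparameterization(self):
        cohort, scores = simulate_simple_cohort(4000, beta_per10=0.2, seed=8)
        per10 = ic.fit_outcome_model(cohort, scores, "c1", "T2D")
        raw_scores = ic.PPSTable(scores=scores.scores / 10.0)  # score/10 as raw
        raw = ic.fit_outcome_model(cohort, raw_scores, "c1", "T2D")
        assert per10.estimate == pytest.approx(raw.estimate / 10.0, rel=1e-6)

    def test_nominal_type_one_error(self):
        """Null effect: rejection rate at alpha=0.05 within binomial bounds."""
        hits = 0
        n_rep = 1000
        for r in range(n_rep):
            cohort, scores = simulate_simple_cohort(400, beta_per10=0.0, seed=1000 + r)
            fit = ic.fit_outcome_model(cohort, scores, "c1", "T2D")
            if fit.usable and fit.p < 0.05:
                hits += 1
        assert 0.035 <= hits / n_rep <= 0.065

    def test_ci_coverage_of_generative_effect(self):
        """The 95% CI covers the generative per-10-unit log OR in >= 93 of
        100 seeded replicates."""
        beta = np.log(1.22)
        hits = 0
        for r in range(100):
            cohort, scores = simulate_simple_cohort(3000, beta_per10=beta, seed=5000 + r)
            fit = ic.fit_outcome_model(cohort, scores, "c1", "T2D")
            if fit.estimate - 1.96 * fit.se <= beta <= fit.estimate + 1.96 * fit.se:
                hits += 1
        assert hits >= 93

    def test_too_few_cases_skipped_with_reason(self):
        cohort, scores = simulate_simple_cohort(200, beta_per10=0.0, seed=9, prevalence=0.02)
        result = ic.fit_outcome_model(cohort, scores, "c1", "T2D", min_cases=10)
        if result.n_cases < 10:
            assert not result.usable and result.reason == "too_few_cases"

    def test_quantitative_outcome_uses_linear_model(self):
        rng = np.random.default_rng(10)
        n = 2000
        ids = [f"I{i}" for i in range(n)]
        score = rng.normal(50, 10, size=n)
        egfr = 90.0 - 0.5 / 10.0 * score + rng.normal(0, 10, size=n)
        cohort = pd.DataFrame({"individual_id": ids, "eGFR": egfr,
                               "age": rng.normal(60, 8, n), "sex": rng.binomial(1, 0.5, n)})
        for j in range(10):
            cohort[f"PC{j + 1}"] = rng.normal(size=n)
        scores = ic.PPSTable(scores=pd.DataFrame({"c1": score}, index=ids))
        result = ic.fit_outcome_model(cohort, scores, "c1", "eGFR")
        assert result.model == "linear"
        assert result.estimate == pytest.approx(-0.5, abs=3 * result.se)

    def test_top_decile_exposure(self):
        cohort, scores = simulate_simple_cohort(8000, beta_per10=0.5, seed=11)
        result = ic.fit_outcome_model(cohort, scores, "c1", "T2D", exposure="top_decile")
        assert result.usable and result.estimate > 0

    def test_pc_screen_drops_unassociated_pcs(self):
        cohort, scores = simulate_simple_cohort(3000, beta_per10=0.2, seed=12)
        screened = ic.fit_outcome_model(cohort, scores, "c1", "T2D", pc_screen=True)
        full = ic.fit_outcome_model(cohort, scores, "c1", "T2D", pc_screen=False)
        assert screened.usable and full.usable
        assert screened.estimate == pytest.approx(full.estimate, abs=0.05)


class TestStratify:
    def _cohort(self, labels):
        return pd.DataFrame({
            "individual_id": [f"I{i}" for i in range(len(labels))],
            "ancestry": labels,
            "t2d_status": np.arange(len(labels)) % 2,
        })

    def test_single_label_is_identity(self):
        cohort = self._cohort(["EUR"] * 40)
        strata = ic.stratify(cohort, "ancestry", min_size=10)
        assert len(strata) == 1
        label, sub, small = strata[0]
        assert label == "EUR" and len(sub) == 40 and not small

    def test_small_stratum_flagged(self):
        cohort = self._cohort(["A"] * 600 + ["B"] * 400)
        strata = dict((lab, small) for lab, _, small in ic.stratify(cohort, "ancestry"))
        assert strata == {"A": False, "B": True}

    def test_partition_conserves_n(self):
        cohort = self._cohort(["A"] * 30 + ["B"] * 20)
        strata = ic.stratify(cohort, "t2d_status", min_size=5)
        assert sum(len(sub) for _, sub, _ in strata) == len(cohort)

    def test_unknown_labels_grouped_as_other(self):
        cohort = self._cohort(["EUR"] * 20 + ["???"] * 5)
        with pytest.warns(UserWarning, match="other"):
            strata = ic.stratify(cohort, "ancestry", min_size=1, allowed=["EUR"])
        labels = {lab for lab, _, _ in strata}
        assert labels == {"EUR", "other"}


class TestIVWFixedEffects:
    def test_equal_se_is_plain_mean(self):
        meta = ic.ivw_fixed_effects([res(0.1, 0.1), res(0.3, 0.1)])
        assert meta.estimate == pytest.approx(0.2)
        assert meta.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_computed_pooling(self):
        meta = ic.ivw_fixed_effects([res(0.1, 0.1), res(0.3, 0.2)])
        assert meta.estimate == pytest.approx(0.14)
        assert meta.se == pytest.approx(0.0894, abs=5e-5)
        assert meta.ci_low == pytest.approx(0.14 - 1.96 * meta.se)
        assert meta.ci_high == pytest.approx(0.14 + 1.96 * meta.se)

    def test_single_study_passthrough(self):
        meta = ic.ivw_fixed_effects([res(0.25, 0.08)])
        assert meta.estimate == pytest.approx(0.25)
        assert meta.se == pytest.approx(0.08)
        assert meta.k == 1 and meta.q == 0.0 and np.isnan(meta.i2)

    def test_pooled_se_below_min_study_se(self):
        meta = ic.ivw_fixed_effects([res(0.1, 0.1), res(0.2, 0.15), res(0.0, 0.3)])
        assert meta.se < 0.1

    def test_pooled_estimate_within_study_range(self):
        rng = np.random.default_rng(0)
        results = [res(b, s) for b, s in zip(rng.normal(size=6), rng.uniform(0.05, 0.4, 6))]
        meta = ic.ivw_fixed_effects(results)
        betas = [r.estimate for r in results]
        assert min(betas) <= meta.estimate <= max(betas)

    def test_k_identical_studies_scales_se(self):
        meta = ic.ivw_fixed_effects([res(0.2, 0.12)] * 4)
        assert meta.estimate == pytest.approx(0.2)
        assert meta.se == pytest.approx(0.12 / 2.0)

    def test_unusable_results_excluded(self):
        bad = res(float("nan"), float("nan"), usable=False, reason="separation")
        meta = ic.ivw_fixed_effects([res(0.1, 0.1), bad])
        assert meta.k == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ic.ivw_fixed_effects([])

    def test_mixed_outcomes_rejected(self):
        with pytest.raises(ValueError):
            ic.ivw_fixed_effects([res(0.1, 0.1, outcome="T2D"), res(0.1, 0.1, outcome="CAD")])

    def test_leave_one_cohort_out_stability(self):
        """Dropping one of several consistent cohorts moves the pooled
        estimate by less than two pooled SEs."""
        rng = np.random.default_rng(3)
        results = [res(0.2 + 0.01 * rng.normal(), 0.05, cohort=f"co{i}") for i in range(5)]
        full = ic.ivw_fixed_effects(results)
        for i in range(5):
            sub = ic.ivw_fixed_effects(results[:i] + results[i + 1:])
            assert abs(sub.estimate - full.estimate) < 2 * full.se


class TestHeterogeneity:
    def test_identical_estimates_zero(self):
        results = [res(0.2, 0.1), res(0.2, 0.1)]
        q, i2 = ic.heterogeneity(results, 0.2)
        assert q == 0.0 and i2 == 0.0

    def test_hand_computed_q_and_i2(self):
        results = [res(0.0, 0.1), res(0.4, 0.1)]
        meta = ic.ivw_fixed_effects(results)
        assert meta.estimate == pytest.approx(0.2)
        assert meta.q == pytest.approx(8.0)
        assert meta.i2 == pytest.approx(87.5)

    def test_i2_clamped_at_zero(self):
        results = [res(0.200, 0.1), res(0.201, 0.1)]
        q, i2 = ic.heterogeneity(results, 0.2005)
        assert q < 1.0 and i2 == 0.0


class TestBonferroni:
    @pytest.mark.parametrize(
        "n_tests,expected", [(1, 0.05), (50, 0.001), (56, 0.05 / 56)]
    )
    def test_threshold_values(self, n_tests, expected):
        assert ic.bonferroni_threshold(n_tests) == pytest.approx(expected)

    def test_printed_truncation(self):
        assert ic.format_threshold(ic.bonferroni_threshold(56)) == "0.0008"

    def test_zero_tests_errors(self):
        with pytest.raises(ValueError):
            ic.bonferroni_threshold(0)


class TestMetaAgainstMetafor:
    def test_cross_check_with_r_metafor(self, tmp_path):
        """Independent oracle: fixed-effects rma in R (metafor) agrees with
        the IVW pooling and I^2 on a small multi-study example."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cross-check cannot run")
        betas = [0.12, 0.05, 0.30, -0.02]
        ses = [0.06, 0.11, 0.09, 0.16]
        script = tmp_path / "fe.R"
        script.write_text(
            "suppressMessages(library(metafor));"
            f"fit <- rma(yi=c({','.join(map(str, betas))}), sei=c({','.join(map(str, ses))}), method='FE');"
            "cat(coef(fit), fit$se, fit$I2, sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        r_beta, r_se, r_i2 = map(float, out.stdout.strip().splitlines())
        meta = ic.ivw_fixed_effects([res(b, s, cohort=f"co{i}") for i, (b, s) in enumerate(zip(betas, ses))])
        assert meta.estimate == pytest.approx(r_beta, rel=1e-6)
        assert meta.se == pytest.approx(r_se, rel=1e-6)
        assert meta.i2 == pytest.approx(r_i2, abs=0.1)


def test_meta_table_shape():
    metas = [ic.ivw_fixed_effects([res(0.1, 0.1), res(0.2, 0.1)])]
    table = meta_table(metas, alpha_threshold=0.05 / 56)
    assert list(table.columns) == [
        "cluster", "outcome", "stratum", "exposure", "k", "estimate", "se", "OR",
        "ci_low", "ci_high", "p", "Q", "I2", "significant",
    ]
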