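import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from claudinlow import (
    CL_LABEL,
    CoxFit,
    OTHER_LABEL,
    SimulationConfig,
    cox_fit,
    forest_table,
    meta_pool,
    simulate_cohort,
)
from oracles import cox_mle_brute


def clinical_frame(times, events, cohort="c1"):
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(times))],
            "time": times,
            "event": events,
            "cohort": cohort,
        }
    )


def calls_series(labels, n):
    return pd.Series(labels, index=[f"S{i}" for i in range(n)])


class TestCoxFit:
    def test_label_symmetric_data_gives_zero_beta(self):
        """A dataset invariant under swapping group labels forces beta = 0."""
        clin = clinical_frame([1.0, 1.0, 2.0, 2.0, 3.0, 3.0], [1] * 6)
        calls = calls_series([CL_LABEL, OTHER_LABEL] * 3, 6)
        fit = cox_fit(clin, calls)
        assert fit.valid
        assert fit.beta == pytest.approx(0.0, abs=1e-6)

    def test_six_subject_toy_matches_partial_likelihood_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        clin = clinical_frame(times, [1] * 6)
        calls = calls_series([CL_LABEL, OTHER_LABEL] * 3, 6)
        fit = cox_fit(clin, calls)
        x = np.array([1.0, 0.0] * 3)
        beta_ref = cox_mle_brute(times, np.ones(6), x)
        assert fit.beta == pytest.approx(beta_ref, abs=1e-4)

    def test_random_tie_free_instances_match_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(5):
            n = 40
            x = (rng.random(n) < 0.4).astype(float)
            times = rng.exponential(scale=1.0 / np.exp(0.5 * x))
            events = (rng.random(n) < 0.8).astype(int)
            if events[x == 1].sum() == 0 or events[x == 0].sum() == 0:
                continue
            clin = clinical_frame(times, events)
            calls = calls_series(np.where(x == 1, CL_LABEL, OTHER_LABEL), n)
            fit = cox_fit(clin, calls)
            assert fit.valid
            assert fit.beta == pytest.approx(cox_mle_brute(times, events, x), abs=1e-4)

    def test_no_events_in_group_flagged_not_raised(self):
        clin = clinical_frame([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        calls = calls_series([CL_LABEL, OTHER_LABEL, CL_LABEL, OTHER_LABEL], 4)
        fit = cox_fit(clin, calls)
        assert not fit.valid
        assert "monotone" in fit.message

    def test_single_subtype_flagged(self):
        clin = clinical_frame([1.0, 2.0], [1, 1])
        fit = cox_fit(clin, calls_series([OTHER_LABEL, OTHER_LABEL], 2))
        assert not fit.valid

    def test_ci_is_exp_of_beta_pm_z_se(self):
        fit = CoxFit(cohort="c", beta=0.5, se=0.2, valid=True)
        lo, hi = fit.ci
        assert lo == pytest.approx(np.exp(0.5 - 1.959964 * 0.2), rel=1e-6)
        assert hi == pytest.approx(np.exp(0.5 + 1.959964 * 0.2), rel=1e-6)

    def test_planted_hazard_ratio_recovered(self):
        cfg = SimulationConfig(
            n_genes=20, n_samples=300, cl_fraction=0.15, log_hr_cl=0.9,
            censoring_rate=0.3, seed=8,
        )
        _, labels, clinical = simulate_cohort(cfg)
        calls = clinical.set_index("sample_id")["subtype_true"]
        fit = cox_fit(clinical, calls)
        assert fit.valid
        assert fit.beta == pytest.approx(0.9, abs=3 * fit.se)


class TestMetaPool:
    def make_fit(self, cohort, beta, se, valid=True):
        return CoxFit(cohort=cohort, beta=beta, se=se, n=100, n_events=60,
                      n_cl=10, valid=valid)

    def test_single_study_passthrough(self):
        meta = meta_pool([self.make_fit("a", 0.7, 0.25)])
        assert meta.beta_fixed == pytest.approx(0.7)
        assert meta.se_fixed == pytest.approx(0.25)
        assert meta.q_stat == 0.0 and meta.i2 == 0.0 and meta.tau2 == 0.0
        assert meta.beta_random == meta.beta_fixed

    def test_hand_inverse_variance_example(self):
        meta = meta_pool([self.make_fit("a", 0.5, 0.2), self.make_fit("b", 1.0, 0.2)])
        assert meta.beta_fixed == pytest.approx(0.75)
        assert meta.se_fixed == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_identical_studies_have_no_heterogeneity(self):
        fits = [self.make_fit(c, 0.6, 0.3) for c in "abcd"]
        meta = meta_pool(fits)
        assert meta.tau2 == 0.0
        assert meta.beta_random == pytest.approx(meta.beta_fixed)
        assert meta.se_random == pytest.approx(meta.se_fixed)

    def test_invariant_to_study_order(self):
        fits = [self.make_fit("a", 0.2, 0.1), self.make_fit("b", 0.9, 0.3),
                self.make_fit("c", 0.5, 0.2)]
        meta1 = meta_pool(fits)
        meta2 = meta_pool(fits[::-1])
        assert meta1.beta_random == pytest.approx(meta2.beta_random)
        assert meta1.tau2 == pytest.approx(meta2.tau2)

    def test_pooling_never_loses_information(self):
        fits = [self.make_fit("a", 0.2, 0.15), self.make_fit("b", 0.4, 0.3)]
        meta = meta_pool(fits)
        assert meta.se_fixed <= min(f.se for f in fits)

    def test_matches_statsmodels_dersimonian_laird(self):
        # heterogeneous studies so the DL tau2 is positive (statsmodels does
        # not clip a negative moment estimate; the convention here does)
        betas = np.array([0.1, 0.9, 0.4, 1.2, 0.6, -0.1])
        ses = np.array([0.15, 0.2, 0.25, 0.15, 0.2, 0.25])
        fits = [self.make_fit(f"c{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]
        meta = meta_pool(fits)
        ref = combine_effects(betas, ses**2, method_re="dl")
        assert meta.beta_fixed == pytest.approx(ref.mean_effect_fe, abs=1e-10)
        assert meta.beta_random == pytest.approx(ref.mean_effect_re, abs=1e-10)
        assert meta.tau2 == pytest.approx(ref.tau2, abs=1e-10)

    def test_invalid_fits_excluded_with_warning(self):
        fits = [self.make_fit("a", 0.5, 0.2),
                self.make_fit("b", np.nan, np.nan, valid=False)]
        with pytest.warns(UserWarning, match="excluded"):
            meta = meta_pool(fits)
        assert meta.k == 1

    def test_no_valid_fits_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            meta_pool([self.make_fit("a", np.nan, np.nan, valid=False)])


class TestForestTable:
    def test_rows_and_weights(self):
        fits = [CoxFit(cohort=c, beta=b, se=0.2, n=50, n_events=30, n_cl=5, valid=True)
                for c, b in zip("abcd", [0.4, 0.6, 0.8, 1.0])]
        meta = meta_pool(fits)
        table = forest_table(meta, fits)
        assert len(table) == 6  # 4 studies + fixed + random
        study_rows = table.iloc[:4]
        assert study_rows["weight_fixed"].sum() == pytest.approx(1.0)

    def test_single_study_random_equals_fixed(self):
        fits = [CoxFit(cohort="a", beta=0.3, se=0.1, n=10, n_events=5, n_cl=2,
                       valid=True)]
        table = forest_table(meta_pool(fits), fits).set_index("study")
        assert table.loc["pooled (random)", "hr"] == pytest.approx(
            table.loc["pooled (fixed)", "hr"]
        )
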