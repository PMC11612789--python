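"""Mixed models, Tukey lsmeans, Fisher omnibus, kappa, backward elimination."""

import warnings

import numpy as np
import pandas as pd
import pytest

from shrewvoc.stats import (backward_eliminate, cohens_kappa, fisher_omnibus,
                            fit_lme, pairwise_lsmeans, simulate_rate_dataset)


def _age_dataset(seed=0, effect=2.0, sd_ind=1.0, n_ind=20, per_ind=10):
    rng = np.random.default_rng(seed)
    ind = np.repeat(np.arange(n_ind), per_ind)
    age = (np.arange(n_ind) % 2)[ind]
    b = rng.normal(0, sd_ind, n_ind)
    y = 1.0 + effect * age + b[ind] + rng.normal(0, 1.0, len(ind))
    return pd.DataFrame({
        "y": y, "age_group": np.where(age == 1, "pup", "adult"),
        "individual": [f"i{i}" for i in ind],
    })


class TestFitLme:
    def test_simulated_age_effect_recovered(self):
        df = _age_dataset(seed=1, effect=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, "y", ["age_group"], "individual")
        est = fit.fe_params["age_group[T.pup]"]
        se = fit.result.bse_fe["age_group[T.pup]"]
        assert abs(est - 2.0) < 3 * se
        assert fit.anova().iloc[0].p_value < 0.001

    def test_constant_response_gives_null_effect(self):
        df = _age_dataset(seed=2)
        df["y"] = 5.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, "y", ["age_group"], "individual")
        assert abs(fit.fe_params["age_group[T.pup]"]) < 1e-6

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf

        df = _age_dataset(seed=3, effect=1.5, sd_ind=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, "y", ["age_group"], "individual")
        ols = smf.ols("y ~ age_group", df).fit()
        assert np.allclose(fit.fe_params.values, ols.params.values, atol=1e-3)

    def test_missing_column_rejected(self):
        df = _age_dataset()
        with pytest.raises(ValueError, match="missing"):
            fit_lme(df, "y", ["age_group"], "no_such_column")


class TestPairwiseLsmeans:
    @staticmethod
    def _three_group(seed=0, means=(0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        n_ind = 30
        ind = np.repeat(np.arange(n_ind), 5)
        g = (np.arange(n_ind) % 3)[ind]
        y = np.asarray(means)[g] + rng.normal(0, 1, len(ind))
        return pd.DataFrame({"y": y, "grp": np.array(["a", "b", "c"])[g],
                             "individual": ind.astype(str)})

    def test_three_level_factor_gives_three_contrasts(self):
        df = self._three_group(seed=1, means=(0, 1, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, "y", ["grp"], "individual")
        cmp = pairwise_lsmeans(fit, "grp")
        assert len(cmp) == 3
        assert (cmp.p_tukey >= cmp.p_unadjusted - 1e-12).all()
        # large separation detected
        assert cmp.set_index("contrast").loc["a - c"].p_tukey < 0.001

    def test_null_type_one_error_controlled(self):
        hits = 0
        reps = 30
        for rep in range(reps):
            df = self._three_group(seed=100 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_lme(df, "y", ["grp"], "individual")
            cmp = pairwise_lsmeans(fit, "grp")
            hits += int((cmp.p_tukey < 0.05).any())
        assert hits <= reps * 0.1

    def test_single_level_factor_rejected(self):
        df = self._three_group()
        df["grp"] = "a"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, "y", ["individual"], "individual")
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_lsmeans(fit, "grp")


class TestFisherOmnibus:
    def test_all_ones_give_zero_statistic(self):
        chi2, df, p = fisher_omnibus([1.0, 1.0, 1.0])
        assert chi2 == pytest.approx(0.0)
        assert df == 6
        assert p == pytest.approx(1.0)

    def test_single_p_of_005(self):
        chi2, df, p = fisher_omnibus([0.05])
        assert chi2 == pytest.approx(5.991, abs=0.001)
        assert df == 2

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fisher_omnibus([0.0, 0.5])

    def test_uniform_p_mean_statistic_matches_chi2_expectation(self):
        rng = np.random.default_rng(0)
        k = 16
        stats = [fisher_omnibus(rng.uniform(size=k))[0] for _ in range(1000)]
        se = np.sqrt(2 * 2 * k / 1000)  # var(chi2_df) = 2 df
        assert abs(np.mean(stats) - 2 * k) < 3 * se


class TestCohensKappa:
    def test_identical_sequences(self):
        labels = ["a", "b", "c", "a"] * 10
        assert cohens_kappa(labels, labels) == pytest.approx(1.0)

    def test_known_confusion_matrix(self):
        # 2x2 confusion [[40, 10], [10, 40]]: p_o = 0.8, p_e = 0.5 -> 0.6
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 40 + ["y"] * 10 + ["x"] * 10 + ["y"] * 40
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_shuffled_labels_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 10_000)
        b = rng.permutation(a)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 500)
        b = np.where(rng.uniform(size=500) < 0.7, a, rng.integers(0, 3, 500))
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cohens_kappa([1, 2], [1, 2, 3])


MAIN = ["sex_composition", "familiarity", "housing_type"]
INTER = ["sex_composition:housing_type", "familiarity:housing_type"]


class TestBackwardElimination:
    def test_null_simulation_drops_to_main_terms(self):
        df = simulate_rate_dataset(n_experiments=48, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, log = backward_eliminate(df, "rate_per_min", MAIN, INTER,
                                          ["individual_1", "individual_2"])
        assert len(log) <= len(INTER)
        terms = [t.term for t in fit.effect_tests]
        assert all(":" not in t for t in terms)

    def test_strong_interaction_retained(self):
        kept = 0
        for rep in range(5):
            df = simulate_rate_dataset(n_experiments=48, seed=200 + rep,
                                       interaction_effect=3.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit, _ = backward_eliminate(df, "rate_per_min", MAIN, INTER,
                                            ["individual_1", "individual_2"])
            terms = [t.term for t in fit.effect_tests]
            kept += int(any("sex_composition" in t and ":" in t for t in terms))
        assert kept >= 4

    def test_mf_boost_detected_as_sex_effect(self):
        df = simulate_rate_dataset(n_experiments=48, seed=3, mf_chirp_boost=1.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, _ = backward_eliminate(df, "rate_per_min", MAIN, INTER,
                                        ["individual_1", "individual_2"])
        sex_p = next(t.p_value for t in fit.effect_tests
                     if t.term == "sex_composition")
        assert sex_p < 0.05
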