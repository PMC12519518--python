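import itertools

import numpy as np
import pandas as pd
import pytest

from bbscreen import (
    auc,
    compare_combinations,
    fit_logistic,
    pava,
    predictiveness_curves,
)
from bbscreen.reference import NEGATIVE, POSITIVE
from bbscreen.risk import SeparationWarning, optimal_curves


def frame_from_binary(x, y):
    # binary predictor encoded through the ApoE4p carrier channel
    return pd.DataFrame(
        {
            "apoe4p_conc": np.where(np.asarray(x) == 1, 1.0, 0.3),
            "composite_amyloid": np.where(np.asarray(y) == 1, POSITIVE, NEGATIVE),
        }
    )


class TestFitLogistic:
    def test_saturated_2x2_equals_log_odds_ratio(self):
        # x=0: 10 neg / 5 pos; x=1: 5 neg / 10 pos  ->  OR = 4
        x = [0] * 15 + [1] * 15
        y = [0] * 10 + [1] * 5 + [0] * 5 + [1] * 10
        model = fit_logistic(frame_from_binary(x, y), ["apoe4p_binary"])
        assert model.coef[0] == pytest.approx(np.log(4.0), abs=1e-6)
        assert model.intercept == pytest.approx(np.log(5 / 10), abs=1e-6)
        assert model.converged

    def test_null_predictor_coefficient_near_zero(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)  # independent of x
        model = fit_logistic(frame_from_binary(x, y), ["apoe4p_binary"])
        assert abs(model.coef[0]) < 0.2

    def test_refit_deterministic(self, tiny_cohort_frame):
        df = tiny_cohort_frame.assign(
            composite_amyloid=np.where(tiny_cohort_frame["amyloid_true"] == 1, POSITIVE, NEGATIVE)
        )
        m1 = fit_logistic(df, ["apoe4p_binary", "log10_ptau181"])
        m2 = fit_logistic(df, ["apoe4p_binary", "log10_ptau181"])
        assert m1.intercept == m2.intercept
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_matches_independent_implementation(self, tiny_cohort_frame):
        import statsmodels.api as sm

        df = tiny_cohort_frame.assign(
            composite_amyloid=np.where(tiny_cohort_frame["amyloid_true"] == 1, POSITIVE, NEGATIVE)
        )
        model = fit_logistic(df, ["apoe4p_binary", "log10_ptau181"])
        X = sm.add_constant(
            np.column_stack(
                [
                    (df["apoe4p_conc"] > 0.668).astype(float),
                    np.log10(df["ptau181"]),
                ]
            )
        )
        ref = sm.Logit(df["amyloid_true"].to_numpy(), X).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-5)
        np.testing.assert_allclose(model.coef, ref.params[1:], atol=1e-5)

    def test_single_class_errors(self):
        df = frame_from_binary([0, 1, 0], [1, 1, 1])
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, ["apoe4p_binary"])

    def test_separation_detected(self):
        df = pd.DataFrame(
            {
                "ptau181": [0.1, 0.2, 0.3, 2.0, 3.0, 4.0],
                "composite_amyloid": [NEGATIVE] * 3 + [POSITIVE] * 3,
            }
        )
        with pytest.warns(SeparationWarning):
            model = fit_logistic(df, ["log10_ptau181"])
        assert model.separation

    def test_fitted_probabilities_in_unit_interval(self, tiny_cohort_frame):
        df = tiny_cohort_frame.assign(
            composite_amyloid=np.where(tiny_cohort_frame["amyloid_true"] == 1, POSITIVE, NEGATIVE)
        )
        model = fit_logistic(df, ["apoe4p_binary", "log10_ptau181"])
        assert ((model.fitted > 0) & (model.fitted < 1)).all()


class TestPava:
    def test_already_monotone_unchanged(self):
        y = [0.1, 0.2, 0.5, 0.9]
        np.testing.assert_allclose(pava(y), y)

    def test_simple_violation_pooled(self):
        np.testing.assert_allclose(pava([0.3, 0.1]), [0.2, 0.2])

    def test_matches_sklearn_isotonic(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.random(rng.integers(2, 30))
            w = rng.uniform(0.5, 2.0, len(y))
            ref = IsotonicRegression().fit_transform(np.arange(len(y)), y, sample_weight=w)
            np.testing.assert_allclose(pava(y, w), ref, atol=1e-10)

    def test_pava_optimality_on_small_grids(self):
        # PAVA minimises squared deviation among monotone fits: compare against
        # brute-force search over monotone candidate vectors on a lattice
        y = np.array([0.4, 0.1, 0.3, 0.8, 0.6])
        fit = pava(y)
        assert (np.diff(fit) >= -1e-12).all()
        fit_err = np.sum((fit - y) ** 2)
        levels = np.linspace(0, 1, 11)
        for cand in itertools.product(levels, repeat=len(y)):
            if all(cand[i] <= cand[i + 1] for i in range(len(y) - 1)):
                assert np.sum((np.asarray(cand) - y) ** 2) >= fit_err - 1e-9

    def test_decreasing_mode(self):
        y = [0.1, 0.5, 0.3]
        fit = pava(y, increasing=False)
        assert (np.diff(fit) <= 1e-12).all()


class TestPredictivenessCurves:
    def test_q_zero_ppv_equals_prevalence(self):
        rng = np.random.default_rng(9)
        fitted = rng.random(50)
        truth = rng.integers(0, 2, 50)
        profile = predictiveness_curves(fitted, truth)
        assert profile.q[0] == 0.0
        assert profile.ppv_raw[0] == pytest.approx(truth.mean())
        assert np.isnan(profile.one_minus_npv_raw[0])  # empty screened-out set

    def test_perfect_ranking_attains_optimal(self):
        # all positives ranked above all negatives, prevalence 0.2
        fitted = np.concatenate([np.linspace(0.05, 0.3, 8), np.linspace(0.6, 0.9, 2)])
        truth = np.array([0] * 8 + [1] * 2)
        profile = predictiveness_curves(fitted, truth)
        np.testing.assert_allclose(profile.ppv_raw[:-1], profile.ppv_opt[:-1], atol=1e-12)
        defined = ~np.isnan(profile.one_minus_npv_raw)
        np.testing.assert_allclose(
            profile.one_minus_npv_raw[defined], profile.one_minus_npv_opt[defined], atol=1e-12
        )

    def test_ten_participant_brute_force(self):
        # hand-assigned risks, exhaustive enumeration of every cut
        fitted = np.array([0.05, 0.10, 0.20, 0.20, 0.30, 0.40, 0.55, 0.70, 0.80, 0.90])
        truth = np.array([0, 0, 1, 0, 0, 1, 0, 1, 1, 1])
        profile = predictiveness_curves(fitted, truth)
        order = np.argsort(fitted, kind="stable")
        y = truth[order]
        f = fitted[order]
        for q, ppv, onpv in zip(profile.q, profile.ppv_raw, profile.one_minus_npv_raw):
            k = int(round(q * 10))
            # ties must stay together: the cut never splits equal fitted values
            if 0 < k < 10:
                assert f[k - 1] != f[k]
            if k > 0:
                assert onpv == pytest.approx(y[:k].mean())
            else:
                assert np.isnan(onpv)
            if k < 10:
                assert ppv == pytest.approx(y[k:].mean())

    def test_conservation_of_positives(self):
        rng = np.random.default_rng(21)
        fitted = rng.random(200)
        truth = rng.integers(0, 2, 200)
        n_pos = truth.sum()
        profile = predictiveness_curves(fitted, truth)
        n = profile.n
        for q, ppv, onpv in zip(profile.q, profile.ppv_raw, profile.one_minus_npv_raw):
            k = int(round(q * n))
            retained = (ppv if not np.isnan(ppv) else 0.0) * (n - k)
            screened = (onpv if not np.isnan(onpv) else 0.0) * k
            assert retained + screened == pytest.approx(n_pos)

    def test_smoothed_curves_monotone(self):
        rng = np.random.default_rng(31)
        fitted = rng.random(300)
        truth = (rng.random(300) < fitted).astype(int)  # calibrated risk
        profile = predictiveness_curves(fitted, truth)
        for curve in (profile.ppv_smooth, profile.one_minus_npv_smooth):
            defined = ~np.isnan(curve)
            assert (np.diff(curve[defined]) >= -1e-12).all()

    def test_optimal_curves_dominate_smoothed(self):
        rng = np.random.default_rng(41)
        fitted = rng.random(500)
        truth = (rng.random(500) < fitted).astype(int)
        profile = predictiveness_curves(fitted, truth)
        defined = ~np.isnan(profile.ppv_smooth)
        assert (profile.ppv_opt[defined] >= profile.ppv_smooth[defined] - 1e-6).all()
        defined = ~np.isnan(profile.one_minus_npv_smooth)
        assert (
            profile.one_minus_npv_opt[defined]
            <= profile.one_minus_npv_smooth[defined] + 1e-6
        ).all()

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both truth classes"):
            predictiveness_curves([0.1, 0.2], [1, 1])

    def test_optimal_curve_shape(self):
        q = np.array([0.0, 0.5, 0.8, 0.9, 1.0])
        ppv, onpv = optimal_curves(q, prevalence=0.2)
        np.testing.assert_allclose(ppv, [0.2, 0.4, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(onpv, [0.0, 0.0, 0.0, 1 / 9, 0.2])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_six_point_hand_count(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2]
        truth = [0, 1, 0, 1, 0, 1]
        # brute-force concordance over all positive-negative pairs
        pos = [s for s, t in zip(scores, truth) if t == 1]
        neg = [s for s, t in zip(scores, truth) if t == 0]
        conc = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        ) / (len(pos) * len(neg))
        assert auc(scores, truth) == pytest.approx(conc)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        scores = rng.random(200)
        truth = rng.integers(0, 2, 200)
        assert auc(scores, truth) == pytest.approx(roc_auc_score(truth, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        scores = rng.random(100)
        truth = rng.integers(0, 2, 100)
        base = auc(scores, truth)
        assert auc(np.exp(5 * scores), truth) == pytest.approx(base)
        assert auc(np.log(scores + 1e-9), truth) == pytest.approx(base)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single truth class"):
            auc([0.1, 0.2], [1, 1])


class TestCompareCombinations:
    @staticmethod
    def _with_outcome(df):
        return df.assign(
            composite_amyloid=np.where(df["amyloid_true"] == 1, POSITIVE, NEGATIVE)
        )

    def test_constructed_ptau_signal_wins(self):
        rng = np.random.default_rng(23)
        n = 2000
        y = rng.integers(0, 2, n)
        df = pd.DataFrame(
            {
                "amyloid_true": y,
                "apoe4p_conc": rng.uniform(0.2, 0.6, n),  # no carrier signal
                "ptau181": np.exp(rng.normal(y * 1.0, 0.3, n)),  # strong signal
                "gfap": rng.uniform(50, 150, n),   # pure noise
                "abeta42": rng.uniform(30, 60, n),
                "abeta40": rng.uniform(200, 400, n),
            }
        )
        table = compare_combinations(self._with_outcome(df))
        assert table.iloc[0]["combo"] == "ptau_apoe4p"
        assert table.iloc[0]["auc"] > table.iloc[1]["auc"]

    def test_generator_controlled_ordering(self, a4_cohort_50k):
        from bbscreen.reference import add_composite_column

        df = add_composite_column(a4_cohort_50k.df.sample(8000, random_state=0))
        df = df[df["composite_amyloid"].isin([POSITIVE, NEGATIVE])]
        table = compare_combinations(df)
        aucs = dict(zip(table["combo"], table["auc"]))
        assert aucs["ptau_apoe4p"] > aucs["gfap_apoe4p"]
        assert aucs["ptau_apoe4p"] > aucs["ab4240_apoe4p"]

    def test_permuted_labels_null(self):
        rng = np.random.default_rng(29)
        n = 3000
        df = pd.DataFrame(
            {
                "amyloid_true": rng.integers(0, 2, n),
                "apoe4p_conc": rng.uniform(0.2, 1.2, n),
                "ptau181": np.exp(rng.normal(0, 0.3, n)),
                "gfap": np.exp(rng.normal(4.5, 0.3, n)),
                "abeta42": np.exp(rng.normal(3.7, 0.2, n)),
                "abeta40": np.exp(rng.normal(5.6, 0.2, n)),
            }
        )
        table = compare_combinations(self._with_outcome(df))
        assert (abs(table["auc"] - 0.5) < 0.05).all()
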