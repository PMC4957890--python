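"""Tests for conditional logistic regression, ROC/AUC, LOOCV, LRT, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, log_expit
from scipy import stats as sps

from parenkin.matched_stats import (
    auc,
    clr_fit_diffs,
    logistic_fit,
    loocv_auc,
    lrt,
    spearman,
)


def grid_search_clr(d: np.ndarray, lo=-10.0, hi=10.0, n=400001) -> float:
    """Dense grid maximiser of the 1-d conditional log-likelihood (oracle)."""
    betas = np.linspace(lo, hi, n)
    ll = log_expit(np.outer(d, betas)).sum(axis=0)
    return float(betas[np.argmax(ll)])


def brute_force_auc(scores, labels) -> float:
    """Exhaustive tie-corrected pair counting (oracle)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConditionalLogit:
    def test_matched_binary_pairs_closed_form(self):
        """Discordant counts f=10, g=5 give the classical OR-hat = f/g = 2."""
        d = np.array([1.0] * 10 + [-1.0] * 5 + [0.0] * 10)
        fit = clr_fit_diffs(d)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(2.0), abs=1e-8)
        assert fit.odds_ratios[0] == pytest.approx(2.0, abs=1e-7)
        assert fit.coef[0] == pytest.approx(grid_search_clr(d), abs=1e-4)

    def test_symmetric_differences_give_zero_coefficient(self):
        d = np.array([0.7, -0.7, 1.3, -1.3, 0.2, -0.2])
        fit = clr_fit_diffs(d)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-10)

    def test_continuous_differences_match_grid_search(self, rng):
        d = rng.normal(0.4, 1.0, size=20)
        fit = clr_fit_diffs(d)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(grid_search_clr(d, -5, 5), abs=1e-4)

    def test_matches_statsmodels_conditional_logit(self, rng):
        """Independent cross-check against the stratified-likelihood fitter."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        n = 60
        x_case = rng.normal(1.0, 1.0, n)
        x_ctrl = rng.normal(0.6, 1.0, n)
        d = np.column_stack([x_case - x_ctrl, rng.normal(size=n)])
        fit = clr_fit_diffs(d)
        y = np.concatenate([np.ones(n), np.zeros(n)])
        exog = np.column_stack(
            [
                np.concatenate([x_case, x_ctrl]),
                np.concatenate([d[:, 1], np.zeros(n)]),
            ]
        )
        groups = np.tile(np.arange(n), 2)
        sm_fit = ConditionalLogit(y, exog, groups=groups).fit(disp=0)
        # agreement is limited by the BFGS tolerance of the reference fitter
        assert fit.coef == pytest.approx(np.asarray(sm_fit.params), abs=1e-4)
        assert fit.se == pytest.approx(np.asarray(sm_fit.bse), abs=1e-4)

    def test_invariant_to_pair_constant_shifts(self, rng):
        # only within-pair differences enter the likelihood, so this holds
        # by construction of the diff interface; check the cohort wrapper
        from parenkin.cohort import MatchedCohort, MatchedPair, SubjectRecord
        from parenkin.matched_stats import clr_fit

        pairs = []
        d = rng.normal(0.5, 1.0, 15)
        shift = rng.normal(0, 5.0, 15)
        for i in range(15):
            base = rng.normal(10.0, 1.0)
            pairs.append(
                MatchedPair(
                    case=SubjectRecord(f"c{i}", "case", 50, 2010, 0, 0, 2, {"m": base + d[i]}),
                    control=SubjectRecord(f"k{i}", "control", 50, 2010, 0, 0, 2, {"m": base}),
                )
            )
        cohort = MatchedCohort(pairs)
        fit1 = clr_fit(cohort, ["m"])
        for i, p in enumerate(cohort.pairs):
            p.case.measures["m"] += shift[i]
            p.control.measures["m"] += shift[i]
        fit2 = clr_fit(cohort, ["m"])
        assert fit2.coef[0] == pytest.approx(fit1.coef[0], rel=1e-9)

    def test_rescaling_covariate_rescales_coefficient(self, rng):
        d = rng.normal(0.4, 1.0, size=30)
        fit1 = clr_fit_diffs(d)
        fit2 = clr_fit_diffs(d / 10.0)
        assert fit2.coef[0] == pytest.approx(10.0 * fit1.coef[0], rel=1e-6)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-10)
        # OR per one *original* unit: the rescaled covariate's unit is 0.1
        fit3 = clr_fit_diffs(d / 10.0, units=[0.1])
        assert fit3.odds_ratios[0] == pytest.approx(fit1.odds_ratios[0], rel=1e-6)

    def test_all_zero_differences_not_identifiable(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            clr_fit_diffs(np.zeros(10))

    def test_one_signed_differences_flag_separation(self):
        fit = clr_fit_diffs(np.abs(np.random.default_rng(0).normal(1.0, 0.2, 25)))
        assert not fit.converged
        assert "separation" in fit.message


class TestLogisticFit:
    def test_binary_covariate_recovers_empirical_rates(self):
        tab = pd.DataFrame(
            {"x": [0] * 20 + [1] * 20, "is_case": [0] * 15 + [1] * 5 + [0] * 8 + [1] * 12}
        )
        fit = logistic_fit(tab, ["x"])
        p0 = fit.fitted[tab.x == 0]
        p1 = fit.fitted[tab.x == 1]
        assert np.allclose(p0, 5 / 20, atol=1e-6)
        assert np.allclose(p1, 12 / 20, atol=1e-6)

    def test_intercept_only_model_fits_case_fraction(self):
        tab = pd.DataFrame({"is_case": [1] * 12 + [0] * 28})
        fit = logistic_fit(tab, [])
        assert np.allclose(fit.fitted, 12 / 40, atol=1e-8)

    def test_loglik_matches_direct_evaluation(self, rng):
        tab = pd.DataFrame(
            {"x": rng.normal(size=40), "z": rng.normal(size=40), "is_case": rng.integers(0, 2, 40)}
        )
        if tab.is_case.nunique() < 2:
            tab.loc[0, "is_case"] = 1 - tab.loc[0, "is_case"]
        fit = logistic_fit(tab, ["x", "z"])
        eta = fit.params[0] + tab[["x", "z"]].to_numpy() @ fit.params[1:]
        y = tab.is_case.to_numpy()
        ll = float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta)))
        assert fit.loglik == pytest.approx(ll, rel=1e-10)

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0], "is_case": [1, 1]}), ["x"])


class TestAUC:
    def test_perfect_separation_gives_one(self):
        r = auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = auc([0.5] * 10, [0, 1] * 5)
        assert r.auc == 0.5

    def test_worked_example(self):
        r = auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)
        assert r.auc == pytest.approx(brute_force_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]))

    @given(st.integers(0, 2**31 - 1).map(np.random.default_rng))
    def test_equals_pair_counting_oracle_with_ties(self, g):
        n = int(g.integers(4, 50))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        g.shuffle(labels)
        scores = g.integers(0, 6, n).astype(float) / 5.0  # coarse grid forces ties
        r = auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_ci_brackets_estimate_and_stays_in_unit_interval(self, rng):
        scores = rng.normal(size=80) + np.repeat([0.0, 0.8], 40)
        labels = np.repeat([0, 1], 40)
        r = auc(scores, labels)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_delong_ci_matches_r_proc(self):
        """Cross-check the DeLong interval against the R pROC reference."""
        import subprocess

        scores = [0.2, 0.35, 0.4, 0.55, 0.6, 0.61, 0.7, 0.82, 0.9, 0.33, 0.45, 0.58]
        labels = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0, 0]
        r = auc(scores, labels)
        rscript = (
            "suppressMessages(library(pROC));"
            f"s <- c({','.join(map(str, scores))});"
            f"l <- c({','.join(map(str, labels))});"
            "ci <- ci.auc(roc(l, s, quiet=TRUE), method='delong');"
            "cat(sprintf('%.10f %.10f %.10f', ci[1], ci[2], ci[3]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        ).stdout.split()
        lo, mid, hi = map(float, out)
        assert r.auc == pytest.approx(mid, abs=1e-10)
        assert r.ci_low == pytest.approx(lo, abs=1e-6)
        assert r.ci_high == pytest.approx(hi, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_roc_curve_monotone(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        r = auc(scores, labels)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)


class TestLOOCV:
    def test_duplicate_rows_make_loocv_equal_in_sample(self):
        base = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 3.0], "is_case": [0, 0, 1, 1]}
        )
        tab = pd.concat([base] * 8, ignore_index=True)  # folds barely move the fit
        full = logistic_fit(tab, ["x"])
        in_sample = auc(full.fitted, full.labels)
        loo = loocv_auc(tab, ["x"])
        assert loo.auc == pytest.approx(in_sample.auc, abs=1e-6)

    def test_pooled_probabilities_equal_manual_fold_refits(self, rng):
        tab = pd.DataFrame(
            {"x": rng.normal(size=14), "is_case": [0, 1] * 7}
        )
        loo = loocv_auc(tab, ["x"])
        manual = np.empty(len(tab))
        for i in range(len(tab)):
            fit = logistic_fit(tab.drop(index=i), ["x"])
            manual[i] = fit.predict(tab.iloc[[i]])[0]
        assert loo.scores == pytest.approx(manual, rel=1e-10)

    def test_null_covariate_gives_chance_level_auc(self, rng):
        tab = pd.DataFrame(
            {"x": rng.normal(size=200), "is_case": rng.permutation([0, 1] * 100)}
        )
        loo = loocv_auc(tab, ["x"])
        assert abs(loo.auc - 0.5) < 0.1

    def test_requires_ten_subjects(self):
        tab = pd.DataFrame({"x": np.arange(6.0), "is_case": [0, 1] * 3})
        with pytest.raises(ValueError, match="n >= 10"):
            loocv_auc(tab, ["x"])


class TestLRT:
    def test_identical_models_give_zero_statistic(self, rng):
        tab = pd.DataFrame({"x": rng.normal(size=30), "is_case": [0, 1] * 15})
        nested = logistic_fit(tab, [])
        full = logistic_fit(tab, ["x"])
        res = lrt(nested, full)
        assert res.statistic >= 0.0
        same = lrt(nested, logistic_fit(tab, ["x"]))
        assert same.statistic == res.statistic

    def test_orthogonal_covariate_statistic_near_zero(self, rng):
        n = 2000
        tab = pd.DataFrame({"is_case": rng.integers(0, 2, n)})
        tab["x"] = rng.normal(size=n)  # independent of outcome
        res = lrt(logistic_fit(tab, []), logistic_fit(tab, ["x"]))
        assert res.statistic < 6.0
        assert res.p_value > 0.01

    def test_non_nested_models_rejected(self, rng):
        tab = pd.DataFrame(
            {"x": rng.normal(size=20), "z": rng.normal(size=20), "is_case": [0, 1] * 10}
        )
        with pytest.raises(ValueError, match="nested"):
            lrt(logistic_fit(tab, ["x"]), logistic_fit(tab, ["z"]))


class TestSpearman:
    def test_strictly_increasing_gives_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(x**3, y)
        assert rho1 == pytest.approx(rho2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_ties_match_manual_rank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
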