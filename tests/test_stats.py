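"""Signed-rank and logistic-regression machinery against independent oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps

from tc_hierarchy.stats import (
    fit_logistic,
    logistic_log_likelihood,
    logistic_score,
    predicted_probability_curve,
    run_unit_analysis,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def naive_signed_rank_V(x, y):
    """Rank-sum recomputation with hand-rolled average ranks."""
    d = [xi - yi for xi, yi in zip(x, y) if xi - yi != 0]
    absd = [abs(v) for v in d]
    order = sorted(range(len(d)), key=lambda i: absd[i])
    ranks = [0.0] * len(d)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # average of positions i..j (1-based)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return sum(r for r, v in zip(ranks, d) if v > 0)


def exact_signed_rank_p(d):
    """Two-sided p by enumerating all 2^n sign assignments (no ties)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    sums = np.array(
        [(ranks * np.array(bits)).sum() for bits in product([0, 1], repeat=n)]
    )
    p = 2 * min((sums <= v_obs).mean(), (sums >= v_obs).mean())
    return min(p, 1.0)


def direct_ml_logistic(y, x, beta0=None):
    """Direct numerical maximization of the written-out log-likelihood."""
    k = x.shape[1]
    beta0 = np.zeros(k) if beta0 is None else beta0

    def negll(b):
        return -logistic_log_likelihood(b, y, x)

    def grad(b):
        return -logistic_score(b, y, x)

    res = optimize.minimize(
        negll, beta0, jac=grad, method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x, -res.fun


def logistic_fixture(seed, n=30, k=2):
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(k)])
    beta = rng.normal(scale=0.8, size=k + 1)
    p = 1 / (1 + np.exp(-(x @ beta)))
    y = rng.binomial(1, p).astype(float)
    if y.min() == y.max():  # regenerate degenerate outcome
        return logistic_fixture(seed + 1000, n, k)
    return y, x


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_all_positive_differences_give_maximal_V(self):
        x = np.arange(1.0, 11.0)
        res = wilcoxon_signed_rank(x, x - 1.0)
        assert res.V == 55  # 10*11/2
        assert res.n_nonzero == 10

    def test_fixed_eight_pair_sample_against_enumeration(self):
        d = np.array([3, -1, 4, -2, 6, 5, -0.5, 2])
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.V == naive_signed_rank_V(d, np.zeros_like(d))
        p_exact = exact_signed_rank_p(d)
        assert abs(res.p_value - p_exact) < 0.03

    def test_identical_samples_undefined(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="no nonzero differences"):
            wilcoxon_signed_rank(x, x)

    def test_V_matches_naive_oracle_with_ties_and_zeros(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(2, 51))
            x = rng.normal(size=m)
            y = x + rng.choice([-1.0, 0.0, 1.0], size=m) * np.round(
                rng.random(m), 1
            )
            if np.all(x - y == 0):
                continue
            res = wilcoxon_signed_rank(x, y)
            assert res.V == pytest.approx(naive_signed_rank_V(x, y))
            assert 0 <= res.V <= res.n_nonzero * (res.n_nonzero + 1) / 2
            assert 0 <= res.p_value <= 1

    def test_matches_r_convention_via_scipy(self):
        """Approximate p with continuity correction equals the standard
        statistical-package behaviour (zero differences dropped)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = int(rng.integers(6, 30))
            x = rng.normal(size=m)
            y = x + rng.normal(size=m)
            mine = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(
                x, y, zero_method="wilcox", correction=True, method="approx"
            )
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_one_sided_alternatives_are_consistent(self):
        x = np.arange(1.0, 11.0)
        y = x - 1.0
        greater = wilcoxon_signed_rank(x, y, alternative="greater")
        less = wilcoxon_signed_rank(x, y, alternative="less")
        assert greater.p_value < 0.01
        assert less.p_value > 0.99


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0, 0.0] * 15)
        design = pd.DataFrame({"intercept": np.ones(30)})
        fit = fit_logistic(y, design)
        assert fit.beta("intercept") == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_direct_likelihood_maximization(self, seed):
        y, x = logistic_fixture(seed)
        design = pd.DataFrame(x, columns=["intercept", "x1", "x2"])
        fit = fit_logistic(y, design)
        beta_hat = np.array([fit.beta(c) for c in design.columns])
        beta_ora, llf_ora = direct_ml_logistic(y, x)
        assert np.max(np.abs(beta_hat - beta_ora)) < 1e-6
        assert fit.log_likelihood == pytest.approx(llf_ora, abs=1e-8)

    def test_score_equations_hold_at_estimates(self):
        for seed in range(5):
            y, x = logistic_fixture(seed, n=120, k=3)
            design = pd.DataFrame(
                x, columns=["intercept", "x1", "x2", "x3"]
            )
            fit = fit_logistic(y, design)
            beta_hat = np.array([fit.beta(c) for c in design.columns])
            assert np.max(np.abs(logistic_score(beta_hat, y, x))) < 1e-6

    def test_information_criteria_identities(self):
        y, x = logistic_fixture(7)
        design = pd.DataFrame(x, columns=["intercept", "x1", "x2"])
        fit = fit_logistic(y, design)
        k, n = 3, len(y)
        assert fit.deviance == pytest.approx(-2 * fit.log_likelihood)
        assert fit.aic == pytest.approx(fit.deviance + 2 * k)
        assert fit.bic == pytest.approx(fit.deviance + k * np.log(n))
        assert all(se > 0 for _, se, _ in fit.coefficients.values())

    def test_perfect_separation_flagged(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"intercept": np.ones(10), "x": x})
        y = (x >= 5).astype(float)
        with pytest.warns(RuntimeWarning):
            fit = fit_logistic(y, design)
        assert not fit.converged
        assert "x" in fit.coefficients  # estimates still reported

    def test_single_class_outcome_rejected(self):
        design = pd.DataFrame({"intercept": np.ones(10)})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(10), design)

    def test_nesting_never_increases_deviance(self):
        """Adding a non-degenerate predictor cannot worsen the deviance."""
        for seed in range(5):
            y, x = logistic_fixture(seed, n=80, k=3)
            small = pd.DataFrame(x[:, :3], columns=["intercept", "x1", "x2"])
            big = pd.DataFrame(x, columns=["intercept", "x1", "x2", "x3"])
            assert (
                fit_logistic(y, big).deviance
                <= fit_logistic(y, small).deviance + 1e-8
            )


# ---------------------------------------------------------------------------
# predicted-probability curves
# ---------------------------------------------------------------------------


class TestPredictedCurve:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(10)
        n = 200
        meas = rng.random(n)
        x = np.column_stack([np.ones(n), rng.normal(size=n), meas])
        eta = 0.5 + 0.3 * x[:, 1] - 2.0 * meas
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        design = pd.DataFrame(x, columns=["intercept", "age", "m"])
        return fit_logistic(y, design)

    def test_negative_coefficient_gives_decreasing_curve(self, fitted):
        assert fitted.beta("m") < 0
        curve = predicted_probability_curve(
            fitted, "m", np.linspace(0, 1, 20), {"age": 0.0}
        )
        probs = [p for _, p in curve]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_probability_half_where_linear_predictor_vanishes(self, fitted):
        g = -(fitted.beta("intercept")) / fitted.beta("m")
        ((_, p),) = predicted_probability_curve(fitted, "m", [g], {"age": 0.0})
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_unknown_term_rejected_and_extrapolation_warns(self, fitted):
        with pytest.raises(ValueError):
            predicted_probability_curve(fitted, "zzz", [0.0], {})
        with pytest.warns(RuntimeWarning, match="outside observed range"):
            predicted_probability_curve(
                fitted, "m", [5.0], {"age": 0.0}, observed_max=1.0
            )


# ---------------------------------------------------------------------------
# unit-level orchestration
# ---------------------------------------------------------------------------


class TestRunUnitAnalysis:
    def test_four_models_share_n_and_covariates(self, small_sim_results):
        ur = small_sim_results.unit_results
        fits = [f for f in ur.models.values() if f is not None]
        assert len(fits) == 4
        assert len({f.n for f in fits}) == 1
        for f in fits:
            assert {"intercept", "age", "lsi_r", "race_minority",
                    "days_in_program"} <= set(f.coefficients)

    def test_row_count_equals_complete_roster(self, small_sim_results):
        ur = small_sim_results.unit_results
        roster = small_sim_results.model.roster
        assert ur.n == int(roster["complete"].sum())

    def test_constant_trajectories_report_no_movement(self):
        n = 30
        rng = np.random.default_rng(2)
        summaries = pd.DataFrame(
            {
                "resident_id": [f"R{i}" for i in range(n)],
                "max_ec": np.ones(n),
                "mean_ec": np.ones(n),
                "lm_max_ec": np.ones(n),
                "lm_mean_ec": np.ones(n),
                "n_weeks": np.full(n, 10),
                "n_lm_weeks": np.full(n, 4),
            }
        )
        roster = pd.DataFrame(
            {
                "resident_id": [f"R{i}" for i in range(n)],
                "graduated": rng.binomial(1, 0.8, n),
                "age": rng.normal(30, 5, n),
                "lsi_r": rng.normal(25, 5, n),
                "race_minority": rng.binomial(1, 0.2, n),
                "days_in_program": rng.integers(30, 200, n),
                "complete": True,
            }
        )
        ur = run_unit_analysis(summaries, roster)
        assert ur.wilcoxon_max is None and ur.wilcoxon_mean is None
        assert any("no hierarchy movement" in note for note in ur.notes)
        assert all(f is None for f in ur.models.values())  # no variation

    def test_small_sample_warning(self, small_sim_results):
        ur = small_sim_results.unit_results
        assert not any("small sample" in note for note in ur.notes)

    def test_summary_text_mentions_all_measures(self, small_sim_results):
        text = small_sim_results.summary()
        for label in (
            "Last Month Maximum Eigenvector Centrality",
            "Maximum Eigenvector Centrality",
            "Days in Program",
            "LSI-R",
            "AIC",
            "Deviance",
        ):
            assert label in text
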