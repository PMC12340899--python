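"""Metrics, Shapley attribution, concordance tables and adjusted logistic
regression, each checked against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from repflow.evalkit import (RegressionSpec, ate_error, auc,
                             concordance_regressions, concordance_table,
                             fit_adjusted_logistic, pehe, pr_auc,
                             shapley_attribution, shapley_ranking)
from repflow.exceptions import InputError, SeparationError
from repflow.synthdata import SynthConfig, generate_cohort


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_pairwise_concordance_oracle(self):
        """Four points, hand-counted: of the 4 positive-negative pairs,
        3 are concordant -> AUC 0.75."""
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.4, 0.35, 0.8]
        pairs = [(s_p, s_n) for s_p, yp in zip(scores, labels) if yp
                 for s_n, yn in zip(scores, labels) if not yn]
        oracle = np.mean([1.0 if p > n else 0.5 if p == n else 0.0
                          for p, n in pairs])
        assert auc(scores, labels) == pytest.approx(oracle)
        assert oracle == 0.75

    def test_independent_scores_near_half(self, rng):
        labels = rng.integers(0, 2, 10000)
        scores = rng.uniform(size=10000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_invariant_to_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 300)
        labels[:5] = 1
        labels[5:10] = 0
        scores = rng.normal(size=300)
        base = auc(scores, labels)
        for f in (lambda s: 3 * s + 7, np.exp, lambda s: np.tanh(s / 2)):
            assert auc(f(scores), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            auc([0.1, 0.9], [1, 1])
        with pytest.raises(InputError):
            pr_auc([0.1, 0.9], [0, 0])


class TestIteMetrics:
    def test_exact_estimates_give_zero_pehe(self, rng):
        v = rng.normal(size=50)
        assert pehe(v, v) == 0.0

    def test_constant_offset_closed_form(self, rng):
        v = rng.normal(size=50)
        assert pehe(v + 0.3, v) == pytest.approx(0.3)
        assert ate_error(v + 0.3, v) == pytest.approx(0.3)

    def test_matches_brute_force_summation(self, rng):
        a, b = rng.normal(size=200), rng.normal(size=200)
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 200)
        assert pehe(a, b) == pytest.approx(brute, abs=1e-12)
        assert ate_error(a, b) == pytest.approx(
            sum(a) / 200 - sum(b) / 200, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            pehe([1.0, 2.0], [1.0])


class TestShapley:
    def test_additive_model_closed_form(self, rng):
        beta = np.array([2.0, -1.0, 0.5, 0.0])
        f = lambda X: X @ beta
        x = rng.normal(size=4)
        bg = rng.normal(size=(30, 4))
        res = shapley_attribution(f, x, bg, n_permutations=10, seed=0)
        expected = beta * (x - bg.mean(axis=0))
        assert np.allclose(res.attributions, expected, atol=1e-12)
        assert np.allclose(res.se, 0.0, atol=1e-12)

    def test_constant_model_attributes_nothing(self, rng):
        f = lambda X: np.full(len(X), 3.3)
        res = shapley_attribution(f, rng.normal(size=5),
                                  rng.normal(size=(10, 5)),
                                  n_permutations=8, seed=0)
        assert np.allclose(res.attributions, 0.0)

    def test_efficiency_identity(self, rng):
        f = lambda X: np.tanh(X[:, 0] * X[:, 1]) + X[:, 2] ** 2
        x = rng.normal(size=3)
        bg = rng.normal(size=(25, 3))
        res = shapley_attribution(f, x, bg, n_permutations=30, seed=1)
        # with full-background averaging the identity is exact per permutation
        assert res.baseline + res.attributions.sum() == pytest.approx(
            res.prediction, abs=1e-10)

    def test_matches_exhaustive_enumeration_on_three_features(self, rng):
        """Interaction model, exact Shapley by summing over all 2^3 subsets."""
        f = lambda X: X[:, 0] * X[:, 1] + 0.5 * X[:, 2] + X[:, 0] ** 2
        x = rng.normal(size=3)
        bg = rng.normal(size=(40, 3))

        def value(subset):
            Z = bg.copy()
            for j in subset:
                Z[:, j] = x[j]
            return float(np.mean(f(Z)))

        exact = np.zeros(3)
        for j in range(3):
            others = [k for k in range(3) if k != j]
            for r in range(3):
                for S in itertools.combinations(others, r):
                    w = (math.factorial(len(S))
                         * math.factorial(2 - len(S)) / math.factorial(3))
                    exact[j] += w * (value(set(S) | {j}) - value(set(S)))
        res = shapley_attribution(f, x, bg, n_permutations=600, seed=2)
        assert np.allclose(res.attributions, exact,
                           atol=np.maximum(3 * res.se, 1e-9) + 1e-12)

    def test_empty_background_rejected(self, rng):
        with pytest.raises(InputError):
            shapley_attribution(lambda X: X.sum(1), rng.normal(size=3),
                                np.zeros((0, 3)))

    def test_ranking_orders_by_mean_abs(self, rng):
        f = lambda X: 5.0 * X[:, 1] + 0.1 * X[:, 0]
        rows = rng.normal(size=(6, 2))
        bg = rng.normal(size=(20, 2))
        ranked = shapley_ranking(f, rows, bg, n_permutations=5, seed=0,
                                 feature_names=["weak", "strong"])
        assert ranked.iloc[0]["feature"] == "strong"


def _toy_ite_cohort():
    """8 encounters with hand-assigned categories, treatments and outcomes."""
    ite = pd.DataFrame({
        "encounter_id": range(8),
        "p_niv": [0.2] * 8, "p_hfnc": [0.3] * 8,
        "ite": [-0.1, -0.1, -0.1, 0.1, 0.1, 0.0005, -0.1, 0.1],
        "category": ["NIV_preferred", "NIV_preferred", "NIV_preferred",
                     "HFNC_preferred", "HFNC_preferred", "indifferent",
                     "NIV_preferred", "HFNC_preferred"],
        "n_samples": [0] * 8, "seed": [0] * 8,
    })
    cohort = pd.DataFrame({
        "encounter_id": range(8),
        "treatment": ["NIV", "NIV", "HFNC", "HFNC", "NIV", "NIV", "NIV",
                      "HFNC"],
        "outcome_imv": [1, 0, 1, 0, 1, 1, 0, 0],
        "outcome_mortality_hospice": [0, 0, 1, 1, 0, 0, 1, 0],
    })
    return ite, cohort


class TestConcordanceTable:
    def test_hand_tally_on_toy_cohort(self):
        ite, cohort = _toy_ite_cohort()
        rates = concordance_table(ite, cohort,
                                  outcomes=("outcome_imv",)).rates
        tab = rates.set_index(["recommended", "group"])
        # NIV-preferred: encounters 0,1,2,6 (5 is indifferent, excluded);
        # received NIV: 0,1,6 -> concordant n=3, events {1,0,0} -> rate 1/3
        assert tab.loc[("NIV", "concordant"), "n"] == 3
        assert tab.loc[("NIV", "concordant"), "rate"] == pytest.approx(1 / 3)
        assert tab.loc[("NIV", "discordant"), "n"] == 1
        assert tab.loc[("NIV", "discordant"), "rate"] == 1.0
        # HFNC-preferred: 3,4,7; received HFNC: 3,7 -> rate 0; discordant 4 -> 1
        assert tab.loc[("HFNC", "concordant"), "n"] == 2
        assert tab.loc[("HFNC", "concordant"), "rate"] == 0.0
        assert tab.loc[("HFNC", "discordant"), "n"] == 1
        assert tab.loc[("HFNC", "discordant"), "rate"] == 1.0

    def test_row_order_invariance(self, rng):
        ite, cohort = _toy_ite_cohort()
        perm = rng.permutation(len(ite))
        shuffled = concordance_table(ite.iloc[perm].reset_index(drop=True),
                                     cohort).rates
        base = concordance_table(ite, cohort).rates
        pd.testing.assert_frame_equal(base, shuffled)

    def test_all_recommendations_followed_flags_empty_discordant(self):
        ite, cohort = _toy_ite_cohort()
        cohort = cohort.copy()
        cohort["treatment"] = ["NIV", "NIV", "NIV", "HFNC", "HFNC", "NIV",
                               "NIV", "HFNC"]
        report = concordance_table(ite, cohort)
        assert "NIV_discordant" in report.empty_groups
        assert "HFNC_discordant" in report.empty_groups


def _nll(beta, X, y):
    eta = X @ beta
    return np.sum(np.logaddexp(0, eta) - y * eta)


class TestAdjustedLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        """10/100 events exposed vs 20/100 unexposed:
        OR = (10*80)/(90*20) = 4/9."""
        exposure = np.repeat([1, 0], 100)
        y = np.concatenate([np.repeat([1, 0], [10, 90]),
                            np.repeat([1, 0], [20, 80])])
        data = pd.DataFrame({"exposed": exposure, "y": y})
        out = fit_adjusted_logistic(
            RegressionSpec(outcome="y", indicators=("exposed",),
                           covariates=()), data)
        or_hat = out.set_index("term").loc["exposed", "odds_ratio"]
        assert or_hat == pytest.approx(4 / 9, abs=1e-6)

    def test_matches_independent_likelihood_optimizer(self, rng):
        n = 300
        X = rng.normal(size=(n, 3))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.5 * X[:, 0]
                                                     - 0.7 * X[:, 2])))).astype(int)
        data = pd.DataFrame(X, columns=["a", "b", "c"])
        data["y"] = y
        out = fit_adjusted_logistic(
            RegressionSpec(outcome="y", indicators=("a",),
                           covariates=("b", "c")), data)
        design = np.column_stack([np.ones(n), X])
        res = minimize(_nll, np.zeros(4), args=(design, y), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.allclose(out["coef"].to_numpy(), res.x, atol=1e-4)

    def test_null_exposure_or_near_one(self, rng):
        n = 10000
        exposure = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        data = pd.DataFrame({"e": exposure, "y": y})
        out = fit_adjusted_logistic(
            RegressionSpec(outcome="y", indicators=("e",), covariates=()),
            data).set_index("term")
        assert out.loc["e", "odds_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_orthogonal_covariate_leaves_exposure_or(self, rng):
        n = 2000
        e = rng.integers(0, 2, n)
        y = (rng.uniform(size=n) < np.where(e == 1, 0.3, 0.2)).astype(int)
        z = rng.normal(size=n)  # independent of both
        d1 = pd.DataFrame({"e": e, "y": y})
        d2 = d1.assign(z=z)
        o1 = fit_adjusted_logistic(RegressionSpec("y", ("e",), ()), d1)
        o2 = fit_adjusted_logistic(RegressionSpec("y", ("e",), ("z",)), d2)
        r1 = o1.set_index("term").loc["e", "odds_ratio"]
        r2 = o2.set_index("term").loc["e", "odds_ratio"]
        assert r2 == pytest.approx(r1, rel=0.02)

    def test_perfect_separation_detected(self):
        data = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1, 0, 1] * 3,
                             "y": [0, 0, 0, 1, 1, 1, 0, 1] * 3})
        with pytest.raises(SeparationError):
            fit_adjusted_logistic(RegressionSpec("y", ("x",), ()), data)

    def test_collinear_columns_named(self, rng):
        n = 100
        x = rng.normal(size=n)
        data = pd.DataFrame({"x1": x, "x2": 2 * x,
                             "y": rng.integers(0, 2, n)})
        with pytest.raises(InputError, match="x2"):
            fit_adjusted_logistic(RegressionSpec("y", ("x1",), ("x2",)), data)


def test_true_preference_concordance_lowers_outcome_rates():
    """End-to-end check of the machinery against ground truth: assign the
    generator's truly preferred treatment to a random half of a confounded
    cohort; the truly-concordant half must have lower outcome rates."""
    cfg = SynthConfig(n_encounters=10000, n_features=10, gamma_treat=1.0,
                      gamma_outcome=1.0, tau_scale=1.5, seed=17)
    cohort, truth = generate_cohort(cfg)
    rng = np.random.default_rng(5)
    coin = rng.integers(0, 2, len(cohort))  # random treatment assignment
    treatment = np.where(coin == 1, "NIV", "HFNC")
    # outcomes drawn from the potential outcome of the assigned arm
    y = np.where(coin == 1,
                 (rng.uniform(size=len(cohort)) < truth.p1).astype(int),
                 (rng.uniform(size=len(cohort)) < truth.p0).astype(int))
    cohort = cohort.assign(treatment=treatment, outcome_imv=y)
    from repflow.flows import categorize
    ite_results = pd.DataFrame({
        "encounter_id": cohort["encounter_id"],
        "p_niv": truth.p1, "p_hfnc": truth.p0, "ite": truth.ite,
        "category": [categorize(v) for v in truth.ite],
        "n_samples": 0, "seed": 0})
    rates = concordance_table(ite_results, cohort,
                              outcomes=("outcome_imv",)).rates
    conc = rates[rates.group == "concordant"]
    disc = rates[rates.group == "discordant"]
    p1, n1 = conc.events.sum() / conc.n.sum(), conc.n.sum()
    p2, n2 = disc.events.sum() / disc.n.sum(), disc.n.sum()
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    assert p1 < p2 - 3 * se


def test_concordance_regressions_full_report(small_cohort, trained_model,
                                             small_inputs):
    cohort, _ = small_cohort
    res = trained_model.predict_ite(small_inputs, method="exact")
    report = concordance_regressions(res, cohort)
    assert set(report.regressions) == {"outcome_imv",
                                       "outcome_mortality_hospice"}
    reg = report.regressions["outcome_imv"].set_index("term")
    for term in ("niv_concordant", "hfnc_concordant", "age", "gender",
                 "sofa", "cci", "risk_score"):
        assert term in reg.index
        assert np.isfinite(reg.loc[term, "odds_ratio"])
        assert 0 <= reg.loc[term, "p_value"] <= 1
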