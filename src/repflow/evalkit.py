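"""Evaluation machinery: prediction metrics, ITE-quality metrics, permutation
Shapley attribution, concordance tables and covariate-adjusted logistic
regression.

The concordance analysis asks whether patients whose received treatment
agrees with the model-recommended one (ITE sign beyond the +-0.001 band)
have better outcomes, adjusting for age, gender, SOFA, CCI and the admission
risk score — an associational adjustment, not a causal identification claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import InputError, SeparationError
from .flows import CATEGORY_HFNC, CATEGORY_INDIFFERENT, CATEGORY_NIV


# -- prediction metrics --------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InputError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision (precision summed at each positive)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise InputError("PR-AUC undefined: no positive labels")
    return float(average_precision_score(labels, scores))


# -- ITE-quality metrics ---------------------------------------------------------

def pehe(ite_hat: np.ndarray, ite_true: np.ndarray) -> float:
    """Root-mean-square error of individual effect estimates."""
    ite_hat, ite_true = _aligned(ite_hat, ite_true)
    return float(np.sqrt(np.mean((ite_hat - ite_true) ** 2)))


def ate_error(ite_hat: np.ndarray, ite_true: np.ndarray) -> float:
    ite_hat, ite_true = _aligned(ite_hat, ite_true)
    return float(np.mean(ite_hat) - np.mean(ite_true))


def _aligned(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise InputError("length mismatch between estimated and true ITEs")
    return a, b


# -- Shapley attribution ---------------------------------------------------------

@dataclass
class ShapleyResult:
    attributions: np.ndarray   # per-feature
    baseline: float            # mean background prediction
    prediction: float          # f(x)
    se: np.ndarray             # Monte-Carlo standard error per feature


def shapley_attribution(predict: Callable[[np.ndarray], np.ndarray],
                        x: np.ndarray, background: np.ndarray,
                        n_permutations: int = 50, seed: int = 0
                        ) -> ShapleyResult:
    """Permutation-sampling Shapley values for a single prediction.

    For each sampled feature ordering, features are switched one by one from
    their background values to the values in ``x``; the marginal change in
    the background-averaged prediction is credited to the switched feature.
    Averaging over all background rows at every coalition makes attributions
    exact for additive models and makes the efficiency identity
    ``baseline + sum(attributions) = predict(x)`` hold per permutation.
    """
    background = np.atleast_2d(np.asarray(background, float))
    if background.shape[0] == 0:
        raise InputError("empty background set")
    x = np.asarray(x, float).ravel()
    d = x.size
    rng = np.random.default_rng(seed)
    nb = background.shape[0]

    contrib = np.zeros((n_permutations, d))
    for p in range(n_permutations):
        order = rng.permutation(d)
        coal = background.copy()          # (nb, d), background everywhere
        prev = float(np.mean(predict(coal)))
        for j in order:
            coal[:, j] = x[j]
            cur = float(np.mean(predict(coal)))
            contrib[p, j] = cur - prev
            prev = cur
    attributions = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations) \
        if n_permutations > 1 else np.zeros(d)
    baseline = float(np.mean(predict(background)))
    prediction = float(np.mean(predict(x[None, :])))
    return ShapleyResult(attributions, baseline, prediction, se)


def shapley_ranking(predict: Callable[[np.ndarray], np.ndarray],
                    rows: np.ndarray, background: np.ndarray,
                    n_permutations: int = 20, seed: int = 0,
                    feature_names: Optional[Sequence[str]] = None
                    ) -> pd.DataFrame:
    """Features ranked by mean absolute Shapley value over ``rows``."""
    rows = np.atleast_2d(np.asarray(rows, float))
    abssum = np.zeros(rows.shape[1])
    for i, r in enumerate(rows):
        res = shapley_attribution(predict, r, background,
                                  n_permutations=n_permutations,
                                  seed=seed + i)
        abssum += np.abs(res.attributions)
    mean_abs = abssum / len(rows)
    names = (list(feature_names) if feature_names is not None
             else [f"f{j}" for j in range(rows.shape[1])])
    out = pd.DataFrame({"feature": names, "mean_abs_shap": mean_abs})
    return out.sort_values("mean_abs_shap", ascending=False,
                           ignore_index=True)


# -- concordance analysis --------------------------------------------------------

@dataclass
class ConcordanceReport:
    rates: pd.DataFrame                    # group sizes and outcome rates
    regressions: Dict[str, pd.DataFrame] = field(default_factory=dict)
    empty_groups: List[str] = field(default_factory=list)


def concordance_table(ite_results: pd.DataFrame, cohort: pd.DataFrame,
                      outcomes: Sequence[str] = ("outcome_imv",
                                                 "outcome_mortality_hospice")
                      ) -> ConcordanceReport:
    """Outcome rates by recommended treatment and concordance status.

    Patients in the indifferent category are excluded.  For each recommended
    treatment r, the concordant group received r and the discordant group
    received the other treatment; empty groups are flagged.
    """
    merged = ite_results.merge(cohort, on="encounter_id", validate="1:1")
    rows, empty = [], []
    for rec, cat in (("NIV", CATEGORY_NIV), ("HFNC", CATEGORY_HFNC)):
        pref = merged[merged["category"] == cat]
        for status in ("concordant", "discordant"):
            grp = pref[(pref["treatment"] == rec) if status == "concordant"
                       else (pref["treatment"] != rec)]
            if len(grp) == 0:
                empty.append(f"{rec}_{status}")
            for oc in outcomes:
                n = len(grp)
                events = int(grp[oc].sum()) if n else 0
                rows.append({"recommended": rec, "group": status,
                             "outcome": oc, "n": n, "events": events,
                             "rate": events / n if n else np.nan})
    return ConcordanceReport(pd.DataFrame(rows), empty_groups=empty)


@dataclass
class RegressionSpec:
    outcome: str
    indicators: Sequence[str] = ("niv_concordant", "hfnc_concordant")
    covariates: Sequence[str] = ("age", "gender", "sofa", "cci", "risk_score")


def fit_adjusted_logistic(spec: RegressionSpec, data: pd.DataFrame
                          ) -> pd.DataFrame:
    """Maximum-likelihood logistic regression with Wald inference.

    Returns one row per term: coefficient, odds ratio, standard error and
    two-sided Wald p-value.  Raises SeparationError on perfect separation and
    InputError naming collinear columns on rank deficiency.
    """
    terms = list(spec.indicators) + list(spec.covariates)
    X = data[terms].to_numpy(float)
    y = data[spec.outcome].to_numpy(float)
    if len(data) <= len(terms) + 1:
        raise InputError("fewer rows than model parameters")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, ["const"] + terms)
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                          tol=1e-8, disp=0)
    except Exception as exc:
        # statsmodels signals separation as PerfectSeparationError or, with a
        # full-rank design, as a singular Hessian during Newton steps
        if ("erfect" in type(exc).__name__ or "erfect" in str(exc)
                or isinstance(exc, np.linalg.LinAlgError)):
            raise SeparationError(str(exc)) from exc
        raise
    coefs = np.asarray(fit.params)
    if np.any(np.abs(coefs[1:]) > 30):
        raise SeparationError("diverging coefficients suggest perfect separation")
    return pd.DataFrame({
        "term": ["const"] + terms,
        "coef": coefs,
        "odds_ratio": np.exp(coefs),
        "se": np.asarray(fit.bse),
        "p_value": np.asarray(fit.pvalues),
    })


def _collinear_columns(design: np.ndarray, names: List[str]) -> List[str]:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    thresh = diag.max() * 1e-10
    return [names[j] for j in np.flatnonzero(diag < thresh)]


def concordance_regressions(ite_results: pd.DataFrame, cohort: pd.DataFrame,
                            outcomes: Sequence[str] = (
                                "outcome_imv", "outcome_mortality_hospice"),
                            covariates: Sequence[str] = (
                                "age", "gender", "sofa", "cci", "risk_score")
                            ) -> ConcordanceReport:
    """Full concordance analysis: rates plus adjusted logistic models.

    One joint model per outcome with both treatments' concordance indicators
    (reference class: discordant patients of either preference); indifferent
    patients are excluded.
    """
    report = concordance_table(ite_results, cohort, outcomes)
    merged = ite_results.merge(cohort, on="encounter_id", validate="1:1")
    merged = merged[merged["category"] != CATEGORY_INDIFFERENT].copy()
    merged["niv_concordant"] = ((merged["category"] == CATEGORY_NIV)
                                & (merged["treatment"] == "NIV")).astype(int)
    merged["hfnc_concordant"] = ((merged["category"] == CATEGORY_HFNC)
                                 & (merged["treatment"] == "HFNC")).astype(int)
    for oc in outcomes:
        spec = RegressionSpec(outcome=oc, covariates=covariates)
        report.regressions[oc] = fit_adjusted_logistic(spec, merged)
    return report


def write_concordance_report(report: ConcordanceReport, rates_path,
                             regression_path=None) -> None:
    report.rates.to_csv(rates_path, sep="\t", index=False)
    if regression_path is not None and report.regressions:
        frames = []
        for oc, df in report.regressions.items():
            df = df.copy()
            df.insert(0, "outcome", oc)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            regression_path, sep="\t", index=False)
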