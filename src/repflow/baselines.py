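"""Reference ITE estimators: plain CFR (Stage-0 heads) and the X-learner.

Both consume the same :class:`~repflow.cfr.ModelInputs` and emit the same
ITE-result table as the flow-based model, so estimators are interchangeable
in the evaluation pipeline.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import (GradientBoostingClassifier,
                              GradientBoostingRegressor)
from sklearn.linear_model import LogisticRegression

from .cfr import HFNC, NIV, ModelInputs, Stage0CFR
from .exceptions import TrainingError
from .flows import build_ite_results


def cfr_ite(model: Stage0CFR, data: ModelInputs, seed: int = 0) -> pd.DataFrame:
    """ITE from the Stage-0 heads alone: p_a = head_a(encode(gate(x)))."""
    phi = model.encode(data.x_dyn, data.tslm, data.x_static)
    p_niv = model.predict_head(phi, NIV)
    p_hfnc = model.predict_head(phi, HFNC)
    return build_ite_results(data, p_niv, p_hfnc, n_samples=0, seed=seed)


class XLearner:
    """Two-stage meta-learner with propensity-weighted blending.

    Stage A fits per-arm outcome models mu0, mu1; stage B fits effect
    regressions tau1 on treated imputed effects ``y - mu0(x)`` and tau0 on
    control imputed effects ``mu1(x) - y``; the final ITE blends
    ``g(x) * tau0(x) + (1 - g(x)) * tau1(x)`` with ``g`` the propensity of
    treatment (NIV) by default.  Base learners are seeded gradient-boosted
    trees; any fit/predict-compatible estimators can be substituted.
    """

    def __init__(self, seed: int = 0,
                 outcome_learner: Optional[Callable] = None,
                 effect_learner: Optional[Callable] = None,
                 propensity_learner: Optional[Callable] = None,
                 fixed_propensity: Optional[float] = None):
        self.seed = seed
        mk_out = outcome_learner or (lambda: GradientBoostingClassifier(
            random_state=seed, max_depth=3, n_estimators=150,
            learning_rate=0.05, subsample=0.8))
        mk_eff = effect_learner or (lambda: GradientBoostingRegressor(
            random_state=seed + 1, max_depth=3, n_estimators=150,
            learning_rate=0.05, subsample=0.8))
        mk_prop = propensity_learner or (lambda: LogisticRegression(max_iter=500))
        self.mu0, self.mu1 = mk_out(), mk_out()
        self.tau0, self.tau1 = mk_eff(), mk_eff()
        self.prop = mk_prop()
        self.fixed_propensity = fixed_propensity
        self._fitted = False

    @staticmethod
    def _proba(model, X) -> np.ndarray:
        if not hasattr(model, "predict_proba"):  # regressor base learner
            return np.asarray(model.predict(X), float)
        p = model.predict_proba(X)
        classes = np.asarray(model.classes_)
        if len(classes) == 1:  # degenerate single-class arm outcome
            return np.full(len(X), float(classes[0]))
        return p[:, int(np.argmax(classes == 1))]

    def fit(self, X: np.ndarray, a: np.ndarray, y: np.ndarray) -> "XLearner":
        X = np.asarray(X, float)
        a = np.asarray(a, int)
        y = np.asarray(y, float)
        if len(np.unique(a)) < 2:
            raise TrainingError("X-learner needs both treatment arms")
        t, c = a == NIV, a == HFNC
        self.mu0.fit(X[c], y[c])
        self.mu1.fit(X[t], y[t])
        d1 = y[t] - self._proba(self.mu0, X[t])   # imputed effects, treated
        d0 = self._proba(self.mu1, X[c]) - y[c]   # imputed effects, control
        self.tau1.fit(X[t], d1)
        self.tau0.fit(X[c], d0)
        if self.fixed_propensity is None:
            self.prop.fit(X, a)
        self._fitted = True
        return self

    def predict_ite(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise TrainingError("XLearner not fitted")
        X = np.asarray(X, float)
        if self.fixed_propensity is not None:
            g = np.full(len(X), float(self.fixed_propensity))
        else:
            g = self._proba(self.prop, X)
        g = np.clip(g, 1e-3, 1 - 1e-3)
        return g * self.tau0.predict(X) + (1.0 - g) * self.tau1.predict(X)


def xlearner_fit(data: ModelInputs, seed: int = 0, **kwargs) -> XLearner:
    X = np.concatenate([data.x_dyn, data.x_static], axis=1)
    return XLearner(seed=seed, **kwargs).fit(X, data.a, data.y)


def xlearner_predict(model: XLearner, data: ModelInputs,
                     seed: int = 0) -> pd.DataFrame:
    X = np.concatenate([data.x_dyn, data.x_static], axis=1)
    ite = model.predict_ite(X)
    # the meta-learner estimates the effect directly; anchor the two
    # potential-outcome probabilities at the per-row average of the arm
    # outcome models so the shared result schema stays consistent
    mid = 0.5 * (XLearner._proba(model.mu1, X) + XLearner._proba(model.mu0, X))
    p_niv = np.clip(mid + ite / 2.0, 0.0, 1.0)
    p_hfnc = np.clip(p_niv - ite, 0.0, 1.0)
    return build_ite_results(data, p_niv, p_hfnc, n_samples=0, seed=seed)
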