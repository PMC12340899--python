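"""Synthetic confounded cohorts with known ground-truth treatment effects.

The generator emulates the causal structure of an observational two-arm
respiratory-support study: measured covariates ``X`` drive both treatment
choice (NIV vs HFNC) and the binary outcome (need for invasive mechanical
ventilation), while a scalar latent severity factor ``u`` — standard normal,
unseen by any estimator — can additionally push both treatment assignment
(``gamma_treat``) and outcome (``gamma_outcome``).  Setting both gammas to
zero yields a cohort with no hidden confounding.

Potential-outcome probabilities are logistic::

    P(Y(a) = 1 | X, u) = sigmoid( h(X) + tau(X) * 1[a = NIV] + gamma_outcome * u )
    P(A = NIV  | X, u) = sigmoid( g(X) + gamma_treat * u )

with ``g`` and ``h`` linear in ``X`` (coefficients fixed per seed) and the
heterogeneous effect ``tau(X) = tau_constant + tau_scale * s(X)`` a linear
score of a covariate subset, so that effect heterogeneity is recoverable by
X-only estimators.  Ground truth is exposed both conditional on ``(X, u)``
and marginalised over ``u | X`` by Gauss-Hermite quadrature — the latter is
the fair recovery target for estimators that only observe ``X``.

Event streams (irregular timestamped measurements per encounter) are
generated separately to exercise the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

N_QUAD = 40  # Gauss-Hermite nodes for marginalising over u | X


@dataclass
class VariableStream:
    """Sampling pattern for one clinical variable in the event-stream generator.

    interval_minutes: mean inter-arrival time; jitter 0 makes it exact.
    missing_prob: per-measurement dropout probability (1.0 removes the variable).
    long_gap_prob: per-measurement chance of a >24 h silent gap, to exercise
        the carry-forward limit.
    """

    interval_minutes: float = 60.0
    jitter: float = 0.0
    missing_prob: float = 0.0
    long_gap_prob: float = 0.0
    level: float = 0.0
    level_sd: float = 1.0
    noise_sd: float = 0.1


@dataclass
class StreamParams:
    variables: Dict[str, VariableStream] = field(default_factory=dict)
    stay_hours: float = 48.0


@dataclass
class SynthConfig:
    n_encounters: int = 1000
    n_features: int = 20
    gamma_treat: float = 0.0
    gamma_outcome: float = 0.0
    tau_scale: float = 0.5
    tau_constant: float = 0.0
    base_rate: float = 0.25
    seed: int = 0
    stream_params: Optional[StreamParams] = None

    def validate(self) -> None:
        if self.n_encounters < 2:
            raise ConfigurationError("n_encounters must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not (0.0 < self.base_rate < 1.0):
            raise ConfigurationError("base_rate must lie in (0, 1)")
        if self.stream_params is not None:
            for name, vs in self.stream_params.variables.items():
                if not (0.0 <= vs.missing_prob <= 1.0):
                    raise ConfigurationError(f"missing_prob for {name} not in [0,1]")
                if vs.interval_minutes <= 0:
                    raise ConfigurationError(f"interval_minutes for {name} must be > 0")


@dataclass
class GroundTruth:
    """True potential-outcome probabilities per encounter.

    ``p1``/``p0`` condition on the realised hidden factor ``u``;
    ``p1_marginal``/``p0_marginal`` integrate over ``u | X`` (= N(0,1), since
    u is independent of X) and are the target for X-only estimators.
    """

    p1: np.ndarray
    p0: np.ndarray
    ite: np.ndarray
    p1_marginal: np.ndarray
    p0_marginal: np.ndarray
    ite_marginal: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "p1": self.p1, "p0": self.p0, "ite_true": self.ite,
            "p1_marginal": self.p1_marginal, "p0_marginal": self.p0_marginal,
            "ite_true_marginal": self.ite_marginal,
        })


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _coefficients(rng: np.random.Generator, p: int) -> dict:
    """Fixed per-seed linear coefficients for g, h, tau and the covariates."""
    beta_g = rng.normal(size=p) / np.sqrt(p)
    beta_h = rng.normal(size=p) / np.sqrt(p)
    k = max(1, p // 4)
    beta_tau = np.zeros(p)
    beta_tau[:k] = rng.normal(size=k) / np.sqrt(k)
    beta_h2 = rng.normal(size=p) / np.sqrt(p)  # secondary-outcome coefficients
    return {"beta_g": beta_g, "beta_h": beta_h, "beta_tau": beta_tau,
            "beta_h2": beta_h2}


def generate_cohort(config: SynthConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Draw one confounded observational cohort.

    Returns the cohort table (features, treatment, outcomes, adjustment
    covariates) and the ground truth.  Bit-reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_encounters, config.n_features
    coef = _coefficients(rng, p)

    X = rng.normal(size=(n, p))
    u = rng.normal(size=n)

    g = X @ coef["beta_g"]
    # intercept puts the marginal outcome prevalence near base_rate
    h0 = np.log(config.base_rate / (1.0 - config.base_rate))
    h = h0 + X @ coef["beta_h"]
    tau = config.tau_constant + config.tau_scale * (X @ coef["beta_tau"])

    p_treat = _sigmoid(g + config.gamma_treat * u)
    A = (rng.uniform(size=n) < p_treat).astype(int)  # 1 = NIV, 0 = HFNC

    p1 = _sigmoid(h + tau + config.gamma_outcome * u)
    p0 = _sigmoid(h + config.gamma_outcome * u)
    y1 = (rng.uniform(size=n) < p1).astype(int)
    y0 = (rng.uniform(size=n) < p0).astype(int)
    y = np.where(A == 1, y1, y0)

    # marginal over u | X = N(0,1) by Gauss-Hermite quadrature
    nodes, weights = np.polynomial.hermite.hermgauss(N_QUAD)
    uq = nodes * np.sqrt(2.0)
    wq = weights / np.sqrt(np.pi)
    p1m = _sigmoid(h[:, None] + tau[:, None] + config.gamma_outcome * uq[None, :]) @ wq
    p0m = _sigmoid(h[:, None] + config.gamma_outcome * uq[None, :]) @ wq

    # secondary outcome: mortality-or-hospice, sharing the treatment effect
    # direction and the hidden factor but with its own covariate profile
    h2 = np.log(config.base_rate / (1.0 - config.base_rate)) - 0.2 + X @ coef["beta_h2"]
    p1_sec = _sigmoid(h2 + tau + config.gamma_outcome * u)
    p0_sec = _sigmoid(h2 + config.gamma_outcome * u)
    y_sec = np.where(A == 1,
                     (rng.uniform(size=n) < p1_sec).astype(int),
                     (rng.uniform(size=n) < p0_sec).astype(int))

    # adjustment covariates: deterministic functions of X plus seeded noise,
    # so the concordance regression stage has realistic per-unit inputs
    sev = X @ coef["beta_h"]  # severity score correlated with outcome risk
    age = np.clip(62.0 + 12.0 * X[:, 0] + rng.normal(scale=4.0, size=n), 18, 100)
    gender = (rng.uniform(size=n) < _sigmoid(0.4 * X[:, 1 % p])).astype(int)
    sofa = np.clip(np.round(2.0 + 1.5 * sev + rng.normal(scale=0.8, size=n)), 0, 24)
    cci = np.clip(np.round(2.5 + 1.2 * X[:, 2 % p] + rng.normal(scale=1.0, size=n)), 0, 15)
    risk_score = _sigmoid(sev + 0.5 * config.gamma_outcome * u
                          + rng.normal(scale=0.3, size=n))

    cohort = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    cohort.insert(0, "encounter_id", np.arange(n))
    cohort["treatment"] = np.where(A == 1, "NIV", "HFNC")
    cohort["outcome_imv"] = y
    cohort["outcome_mortality_hospice"] = y_sec
    cohort["age"] = age
    cohort["gender"] = gender
    cohort["sofa"] = sofa
    cohort["cci"] = cci
    cohort["risk_score"] = risk_score

    truth = GroundTruth(p1=p1, p0=p0, ite=p1 - p0,
                        p1_marginal=p1m, p0_marginal=p0m, ite_marginal=p1m - p0m)
    return cohort, truth


def feature_columns(cohort: pd.DataFrame) -> List[str]:
    return [c for c in cohort.columns if c.startswith("x")]


def generate_event_streams(config: SynthConfig) -> pd.DataFrame:
    """Generate long-format irregular event streams for each encounter.

    Returns a DataFrame with columns (encounter_id, variable,
    timestamp_minutes, value).  Per encounter and variable, measurement times
    follow the configured inter-arrival pattern over the stay; values move
    around a per-encounter latent level with a slow trend.  With probability
    ``long_gap_prob`` a measurement is followed by a silent gap longer than
    24 hours so downstream carry-forward limits are exercised.
    """
    config.validate()
    if config.stream_params is None:
        raise ConfigurationError("stream_params must be set to generate event streams")
    sp = config.stream_params
    rng = np.random.default_rng(config.seed + 1)
    stay_min = sp.stay_hours * 60.0

    rows: List[tuple] = []
    for enc in range(config.n_encounters):
        for name, vs in sp.variables.items():
            level = vs.level + vs.level_sd * rng.normal()
            slope = 0.01 * vs.level_sd * rng.normal()
            t = 0.0
            while t < stay_min:
                if rng.uniform() >= vs.missing_prob:
                    value = level + slope * (t / 60.0) + vs.noise_sd * rng.normal()
                    rows.append((enc, name, t, value))
                gap = vs.interval_minutes
                if vs.jitter > 0:
                    gap *= max(0.05, 1.0 + vs.jitter * rng.normal())
                if vs.long_gap_prob > 0 and rng.uniform() < vs.long_gap_prob:
                    gap += (24.0 + 6.0 * rng.uniform()) * 60.0
                t += gap
    return pd.DataFrame(rows, columns=["encounter_id", "variable",
                                       "timestamp_minutes", "value"])


# -- delimited-text I/O --------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.frame().to_csv(path, sep="\t", index=False)


def write_event_streams(streams: pd.DataFrame, path) -> None:
    streams.to_csv(path, sep="\t", index=False)


def read_event_streams(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
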