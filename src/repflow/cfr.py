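"""Stage 0: counterfactual-regression representation learning.

A TSLM gate downweights stale dynamic features, a shared feed-forward
encoder maps the gated features to a representation ``phi``, and two
treatment-specific heads predict the binary outcome.  Training minimises

    L0 = factual binary cross-entropy + lambda * IPM(phi | NIV, phi | HFNC)

where the IPM term is an entropic-regularised optimal-transport (Sinkhorn)
distance between the two arms' representation distributions, encouraging the
encoder to balance measured confounders across arms.

The gate has the form ``w_i = exp(-softplus(d_i) * tslm_i)`` with learnable
``d_i``: weight 1 for a freshly measured variable, monotone non-increasing
in staleness, and the identity in the limit ``softplus(d_i) -> 0``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from .exceptions import (ConfigurationError, DivergenceError, InputError,
                         TrainingError)
from .nn import MLP, Adam, get_params_vector, minibatches, set_params_vector

NIV, HFNC = 1, 0  # treatment coding throughout the package


@dataclass
class CFRHyperparams:
    rep_layer_sizes: List[int] = field(default_factory=lambda: [32, 16])
    head_layer_sizes: List[int] = field(default_factory=lambda: [16])
    lambda_ipm: float = 0.5
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 25
    batch_size: int = 128
    weight_decay: float = 1e-4
    val_fraction: float = 0.2
    ipm_reg: float = 0.1
    ipm_iters: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_ipm < 0:
            raise ConfigurationError("lambda_ipm must be >= 0")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be < max_epochs")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")


@dataclass
class ModelInputs:
    """Arrays consumed by the model: dynamic features with per-feature TSLM,
    static features, treatment (1 = NIV, 0 = HFNC) and binary outcome."""

    x_dyn: np.ndarray             # (n, d_dyn)
    tslm: np.ndarray              # (n, d_dyn), hours, >= 0
    x_static: np.ndarray          # (n, d_static)
    a: np.ndarray                 # (n,) in {0, 1}
    y: np.ndarray                 # (n,) in {0, 1}
    encounter_id: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(self.tslm < 0):
            raise InputError("negative TSLM values")
        n = len(self.a)
        for arr in (self.x_dyn, self.tslm, self.x_static, self.y):
            if len(arr) != n:
                raise InputError("inconsistent row counts in ModelInputs")

    @property
    def n(self) -> int:
        return len(self.a)

    def subset(self, idx: np.ndarray) -> "ModelInputs":
        return ModelInputs(self.x_dyn[idx], self.tslm[idx], self.x_static[idx],
                           self.a[idx], self.y[idx],
                           None if self.encounter_id is None
                           else self.encounter_id[idx])


def inputs_from_cohort(cohort: pd.DataFrame,
                       feature_cols: Optional[Sequence[str]] = None,
                       tslm_cols: Optional[Sequence[str]] = None,
                       static_cols: Sequence[str] = (),
                       outcome: str = "outcome_imv") -> ModelInputs:
    """Build model inputs from a cohort table.

    Without explicit ``tslm_cols`` all features are treated as fresh
    (TSLM = 0), which makes the gate the identity at initialisation.
    """
    if feature_cols is None:
        feature_cols = [c for c in cohort.columns if c.startswith("x")]
    x_dyn = cohort[list(feature_cols)].to_numpy(float)
    if tslm_cols is not None:
        tslm = cohort[list(tslm_cols)].to_numpy(float)
    else:
        tslm = np.zeros_like(x_dyn)
    x_static = (cohort[list(static_cols)].to_numpy(float)
                if static_cols else np.zeros((len(cohort), 0)))
    a = np.where(cohort["treatment"].to_numpy(str) == "NIV", NIV, HFNC)
    y = cohort[outcome].to_numpy(int)
    enc = cohort["encounter_id"].to_numpy() if "encounter_id" in cohort else None
    return ModelInputs(x_dyn, tslm, x_static, a, y, enc)


# -- IPM: entropic optimal transport ------------------------------------------

def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = np.sum(a ** 2, 1)[:, None] + np.sum(b ** 2, 1)[None, :] - 2 * a @ b.T
    return np.sqrt(np.maximum(d2, 0.0))


def _sinkhorn_plan(C: np.ndarray, reg: float, n_iters: int,
                   tol: float = 1e-9) -> np.ndarray:
    """Log-domain Sinkhorn with uniform marginals; returns the transport plan."""
    na, nb = C.shape
    log_mu = -np.log(na)
    log_nu = -np.log(nb)
    f = np.zeros(na)
    g = np.zeros(nb)
    for it in range(n_iters):
        M = (-C + g[None, :]) / reg
        f = reg * log_mu - reg * _logsumexp(M, axis=1)
        M = (-C + f[:, None]) / reg
        g = reg * log_nu - reg * _logsumexp(M, axis=0)
        if it % 10 == 9 or it == n_iters - 1:
            P = np.exp((-C + f[:, None] + g[None, :]) / reg)
            err = max(np.max(np.abs(P.sum(1) - 1.0 / na)),
                      np.max(np.abs(P.sum(0) - 1.0 / nb)))
            if err < tol:
                break
    return np.exp((-C + f[:, None] + g[None, :]) / reg)


def _logsumexp(M: np.ndarray, axis: int) -> np.ndarray:
    mx = M.max(axis=axis, keepdims=True)
    out = mx + np.log(np.sum(np.exp(M - mx), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def _ot_cost(a: np.ndarray, b: np.ndarray, reg: float, n_iters: int,
             tol: float = 1e-13) -> float:
    C = _pairwise_dist(a, b)
    P = _sinkhorn_plan(C, reg, n_iters, tol=tol)
    return float(np.sum(P * C))


def ipm_distance(phi_a: np.ndarray, phi_b: np.ndarray, reg: float = 0.1,
                 n_iters: int = 1000, method: str = "sinkhorn",
                 tol: float = 1e-13) -> float:
    """Integral probability metric between two representation samples.

    ``method='sinkhorn'``: debiased entropic optimal transport,
    ``S(a,b) - (S(a,a) + S(b,b)) / 2`` with Euclidean ground cost, clipped at
    zero.  ``method='exact1d'``: exact 1-D Wasserstein-1 via sorted samples
    (requires 1-D, equal-size inputs); used as an independent oracle.
    """
    phi_a = np.atleast_2d(np.asarray(phi_a, float))
    phi_b = np.atleast_2d(np.asarray(phi_b, float))
    if phi_a.shape[0] == 0 or phi_b.shape[0] == 0:
        raise InputError("ipm_distance requires non-empty samples")
    if method == "exact1d":
        if phi_a.shape[1] != 1 or phi_b.shape[1] != 1:
            raise InputError("exact1d requires 1-D samples")
        if phi_a.shape[0] != phi_b.shape[0]:
            raise InputError("exact1d requires equal sample sizes")
        return float(np.mean(np.abs(np.sort(phi_a[:, 0]) - np.sort(phi_b[:, 0]))))
    if method != "sinkhorn":
        raise ConfigurationError(f"unknown IPM method {method!r}")
    s_ab = _ot_cost(phi_a, phi_b, reg, n_iters, tol)
    s_aa = _ot_cost(phi_a, phi_a, reg, n_iters, tol)
    s_bb = _ot_cost(phi_b, phi_b, reg, n_iters, tol)
    return max(0.0, s_ab - 0.5 * (s_aa + s_bb))


# -- model ---------------------------------------------------------------------

class Stage0CFR:
    """Gate + shared encoder + two outcome heads."""

    def __init__(self, n_dynamic: int, n_static: int, hp: CFRHyperparams):
        hp.validate()
        self.hp = hp
        self.n_dynamic = n_dynamic
        self.n_static = n_static
        rng = np.random.default_rng(hp.seed)
        # gate decay init near zero => near-identity gate at start
        self.gate_d = Tensor(np.full(n_dynamic, -4.0), requires_grad=True)
        self.encoder = MLP(n_dynamic + n_static, hp.rep_layer_sizes[:-1],
                           hp.rep_layer_sizes[-1], rng)
        self.head_niv = MLP(hp.rep_layer_sizes[-1], hp.head_layer_sizes, 1, rng)
        self.head_hfnc = MLP(hp.rep_layer_sizes[-1], hp.head_layer_sizes, 1, rng)
        self.history: List[dict] = []
        self._scaler: Optional[Tuple[np.ndarray, np.ndarray]] = None

    # gate weight as plain numpy, for inspection and tests
    def gate_weights(self, tslm: np.ndarray) -> np.ndarray:
        d = np.log1p(np.exp(self.gate_d.data))  # softplus
        return np.exp(-d * np.asarray(tslm, float))

    @property
    def parameters(self) -> List[Tensor]:
        return ([self.gate_d] + self.encoder.parameters
                + self.head_niv.parameters + self.head_hfnc.parameters)

    def _standardize(self, x: np.ndarray, fit: bool = False) -> np.ndarray:
        if fit:
            mu = x.mean(0)
            sd = x.std(0)
            sd[sd < 1e-8] = 1.0
            self._scaler = (mu, sd)
        if self._scaler is None:
            return x
        mu, sd = self._scaler
        return (x - mu) / sd

    def tslm_gate(self, x_dyn, tslm) -> Tensor:
        """Multiply each dynamic feature by exp(-softplus(d) * tslm)."""
        tslm_arr = tslm.data if isinstance(tslm, Tensor) else np.asarray(tslm, float)
        if np.any(tslm_arr < 0):
            raise InputError("negative TSLM passed to gate")
        x_dyn = Tensor._lift(x_dyn)
        decay = ad.softplus(self.gate_d)
        w = ad.exp(decay * Tensor(-tslm_arr))
        return x_dyn * w

    def encode(self, x_dyn: np.ndarray, tslm: np.ndarray,
               x_static: np.ndarray, standardized: bool = False) -> Tensor:
        x = np.concatenate([np.asarray(x_dyn, float),
                            np.asarray(x_static, float)], axis=1)
        if not standardized:
            x = self._standardize(x)
        gated = self.tslm_gate(Tensor(x[:, :self.n_dynamic]), tslm)
        full = ad.concatenate([gated, Tensor(x[:, self.n_dynamic:])], axis=1)
        return self.encoder(full)

    def head_logit(self, phi: Tensor, a: int) -> Tensor:
        if a == NIV:
            return self.head_niv(phi)
        if a == HFNC:
            return self.head_hfnc(phi)
        raise InputError(f"unknown treatment code {a!r}")

    def predict_head(self, phi, a: int) -> np.ndarray:
        """Outcome probability from a representation under treatment ``a``."""
        phi = Tensor._lift(phi)
        logit = self.head_logit(phi, a)
        return ad.sigmoid(logit).data.ravel()

    def predict_proba(self, data: ModelInputs, a: int) -> np.ndarray:
        phi = self.encode(data.x_dyn, data.tslm, data.x_static)
        return self.predict_head(phi, a)

    def representations(self, data: ModelInputs) -> np.ndarray:
        return self.encode(data.x_dyn, data.tslm, data.x_static).data

    # -- training --------------------------------------------------------------
    def _factual_bce(self, phi: Tensor, a: np.ndarray, y: np.ndarray) -> Tensor:
        """Mean BCE where each row is scored by its own arm's head."""
        terms = []
        n = len(a)
        for code, head in ((NIV, self.head_niv), (HFNC, self.head_hfnc)):
            idx = np.flatnonzero(a == code)
            if idx.size == 0:
                continue
            logit = head(phi[idx]).reshape(-1)
            yt = Tensor(y[idx].astype(float))
            terms.append((ad.softplus(logit) - yt * logit).sum())
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total / float(n)

    def _ipm_term(self, phi: Tensor, a: np.ndarray) -> Optional[Tensor]:
        """Entropic-OT distance between arm representations, differentiable
        through the cost matrix with the transport plan held fixed."""
        idx1 = np.flatnonzero(a == NIV)
        idx0 = np.flatnonzero(a == HFNC)
        if idx1.size == 0 or idx0.size == 0:
            return None  # single-arm minibatch: skip the IPM term this step
        pa, pb = phi[idx1], phi[idx0]
        P = _sinkhorn_plan(_pairwise_dist(pa.data, pb.data),
                           self.hp.ipm_reg, self.hp.ipm_iters, tol=1e-6)
        d = pa.reshape(idx1.size, 1, -1) - pb.reshape(1, idx0.size, -1)
        dist = ad.sqrt((d * d).sum(axis=2) + 1e-12)
        return (Tensor(P) * dist).sum()

    def loss(self, data: ModelInputs, lambda_ipm: Optional[float] = None) -> Tensor:
        """Differentiable minibatch loss; the IPM broadcast is O(n_a*n_b*dim),
        so this is meant for minibatch-sized inputs."""
        lam = self.hp.lambda_ipm if lambda_ipm is None else lambda_ipm
        phi = self.encode(data.x_dyn, data.tslm, data.x_static)
        total = self._factual_bce(phi, data.a, data.y)
        if lam > 0:
            ipm = self._ipm_term(phi, data.a)
            if ipm is not None:
                total = total + lam * ipm
        return total

    def eval_loss(self, data: ModelInputs, max_ipm_per_arm: int = 128) -> float:
        """Loss for monitoring/early stopping: numpy-only, with the IPM term
        evaluated on a deterministic subsample of each arm."""
        phi = self.representations(data)
        logit_niv = self.head_logit(Tensor(phi), NIV).data.ravel()
        logit_hfnc = self.head_logit(Tensor(phi), HFNC).data.ravel()
        logit = np.where(data.a == NIV, logit_niv, logit_hfnc)
        bce = np.mean(np.maximum(logit, 0) - data.y * logit
                      + np.log1p(np.exp(-np.abs(logit))))
        total = float(bce)
        if self.hp.lambda_ipm > 0:
            pa = phi[data.a == NIV][:max_ipm_per_arm]
            pb = phi[data.a == HFNC][:max_ipm_per_arm]
            if len(pa) and len(pb):
                total += self.hp.lambda_ipm * ipm_distance(
                    pa, pb, reg=self.hp.ipm_reg, n_iters=50, tol=1e-6)
        return total


def train_stage0(data: ModelInputs, hp: CFRHyperparams,
                 val_data: Optional[ModelInputs] = None) -> Stage0CFR:
    """Fit the Stage-0 model with Adam, minibatching and early stopping.

    If ``val_data`` is None a seeded validation split stratified by
    (treatment, outcome) is carved out of ``data``.  Raises TrainingError on
    single-arm cohorts and DivergenceError on non-finite losses.
    """
    hp.validate()
    if len(np.unique(data.a)) < 2:
        raise TrainingError("training cohort contains a single treatment arm")
    rng = np.random.default_rng(hp.seed)
    if val_data is None:
        tr_idx, va_idx = stratified_split(data.a, data.y, hp.val_fraction, rng)
        train, val = data.subset(tr_idx), data.subset(va_idx)
    else:
        train, val = data, val_data

    model = Stage0CFR(data.x_dyn.shape[1], data.x_static.shape[1], hp)
    # fit the standardizer on the training split only
    model._standardize(np.concatenate([train.x_dyn, train.x_static], 1), fit=True)
    opt = Adam(model.parameters, lr=hp.learning_rate,
               weight_decay=hp.weight_decay)

    best = (np.inf, get_params_vector(model.parameters))
    stall = 0
    for epoch in range(hp.max_epochs):
        for idx in minibatches(train.n, hp.batch_size, rng):
            opt.zero_grad()
            loss = model.loss(train.subset(idx))
            if not np.isfinite(loss.data):
                raise DivergenceError("non-finite Stage-0 loss",
                                      {"epoch": epoch})
            loss.backward()
            opt.step()
        val_loss = model.eval_loss(val)
        train_loss = model.eval_loss(train)
        model.history.append({"epoch": epoch, "train_loss": train_loss,
                              "val_loss": val_loss})
        if val_loss < best[0] - 1e-6:
            best = (val_loss, get_params_vector(model.parameters))
            stall = 0
        else:
            stall += 1
            if stall > hp.patience:
                break
    set_params_vector(model.parameters, best[1])
    return model


def stratified_split(a: np.ndarray, y: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded split stratified by (treatment, outcome) cells."""
    hold = []
    for code in np.unique(a):
        for lab in np.unique(y):
            cell = np.flatnonzero((a == code) & (y == lab))
            cell = rng.permutation(cell)
            k = max(1, int(round(fraction * len(cell)))) if len(cell) else 0
            hold.append(cell[:k])
    va = np.sort(np.concatenate(hold)) if hold else np.array([], int)
    tr = np.setdiff1d(np.arange(len(a)), va)
    return tr, va


def finetune(model: Stage0CFR, external: ModelInputs, fraction: float = 0.25,
             hp: Optional[CFRHyperparams] = None,
             max_epochs: Optional[int] = None
             ) -> Tuple[Stage0CFR, np.ndarray, np.ndarray]:
    """Continue optimisation on a seeded random fraction of an external cohort.

    Returns ``(model, tune_idx, eval_idx)``; the evaluation rows are never
    trained on.  ``fraction=1.0`` leaves an empty evaluation set (warned).
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("finetune fraction must lie in (0, 1]")
    hp = hp or model.hp
    n_epochs = hp.max_epochs if max_epochs is None else max_epochs
    rng = np.random.default_rng(hp.seed + 1)
    perm = rng.permutation(external.n)
    k = int(round(fraction * external.n))
    tune_idx, eval_idx = perm[:k], perm[k:]
    if eval_idx.size == 0:
        import warnings
        warnings.warn("finetune fraction=1.0 leaves no held-out evaluation rows")
    if n_epochs == 0 or tune_idx.size == 0:
        return model, tune_idx, eval_idx

    model = copy.deepcopy(model)
    tune = external.subset(tune_idx)
    opt = Adam(model.parameters, lr=hp.learning_rate * 0.3,
               weight_decay=hp.weight_decay)
    for epoch in range(n_epochs):
        for idx in minibatches(tune.n, hp.batch_size, rng):
            opt.zero_grad()
            loss = model.loss(tune.subset(idx))
            if not np.isfinite(loss.data):
                raise DivergenceError("non-finite fine-tuning loss",
                                      {"epoch": epoch})
            loss.backward()
            opt.step()
    return model, tune_idx, eval_idx
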