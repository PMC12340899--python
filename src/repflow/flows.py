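"""Stages 1-2: conditional normalizing flows over the outcome, hidden-
confounding adjustment, and Monte-Carlo ITE inference.

The binary outcome is lifted to a continuous target by uniform
dequantization, ``y* = y + v`` with ``v ~ U[0,1)``, decoded back by the rule
``event <=> y* >= 1``.  A conditional 1-D flow is a stack of monotone
rational-quadratic-spline and affine transforms whose parameters come from a
conditioner network applied to the context — ``(phi, a)`` for the Stage-1
outcome flow, ``phi`` alone for the Stage-2 latent-adjustment flow.

Direction conventions: the *analytic*, trainable direction maps data to
latent (``normalize``); the generative direction (latent to data, the
"forward" of :func:`transform`) inverts it by bisection, which is exact to
floating-point tolerance because the map is strictly monotone in 1-D.

Stage 1 maximises the conditional log-likelihood of the dequantized observed
outcomes given ``(phi, a)``.  Stage 2, with Stage 1 frozen, trains a second
flow conditioned on ``phi`` only so that composing stage-2 forward with
stage-1 forward again maximises the likelihood of the observed outcomes —
shifting the latent distribution toward the treatment-free (interventional)
one.  At inference, latent draws are pushed through stage 2 then stage 1 and
averaged; because the composed map is monotone, the event indicator
``y* >= 1`` for a draw ``u~`` is equivalent to ``u~ >= g2(g1(1))``, which the
sampler uses directly (and which also yields the closed-form,
infinite-sample probability ``1 - Phi(g2(g1(1)))``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _autodiff as ad
from ._autodiff import Tensor
from .cfr import (NIV, HFNC, CFRHyperparams, ModelInputs, Stage0CFR,
                  stratified_split, train_stage0)
from .exceptions import (ConfigurationError, DivergenceError, InputError,
                         TrainingError)
from .nn import MLP, Adam, get_params_vector, minibatches, set_params_vector

LOG_2PI = float(np.log(2.0 * np.pi))
_DERIV_SHIFT = float(np.log(np.e - 1.0))  # softplus(x + shift) = 1 at x = 0


@dataclass
class FlowHyperparams:
    depth: int = 2                  # number of (spline, affine) blocks
    n_bins: int = 8
    bound: float = 4.0              # spline interval [-bound, bound]
    family: str = "spline"          # "spline" or "affine"
    cond_hidden: List[int] = field(default_factory=lambda: [32])
    learning_rate: float = 1e-2
    max_epochs: int = 150
    patience: int = 25
    batch_size: int = 256
    weight_decay: float = 1e-4
    val_fraction: float = 0.2
    early_stop: bool = True  # False: run to convergence on the training NLL
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("flow depth must be >= 1")
        if self.family not in ("spline", "affine"):
            raise ConfigurationError(f"unknown flow family {self.family!r}")
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")


def _softmax(t: Tensor) -> Tensor:
    m = Tensor(t.data.max(axis=1, keepdims=True))
    e = ad.exp(t - m)
    return e / e.sum(axis=1, keepdims=True)


class _AffineLayer:
    """z = x * exp(s) + t; identity at zero parameters."""

    n_params = 2

    def apply(self, x, params: Tensor) -> Tuple[Tensor, Tensor]:
        x = Tensor._lift(x)
        s = params[:, 0]
        t = params[:, 1]
        z = x * ad.exp(s) + t
        return z, s  # log|dz/dx| = s


class _RQSplineLayer:
    """Monotone rational-quadratic spline on [-bound, bound], identity tails.

    Parametrisation follows the standard neural-spline construction: softmax
    bin widths/heights, softplus interior knot derivatives with boundary
    derivatives fixed at 1; all-zero parameters give the identity map.
    """

    def __init__(self, n_bins: int, bound: float):
        self.K = n_bins
        self.B = bound
        self.n_params = 3 * n_bins - 1
        self._cum = np.triu(np.ones((n_bins, n_bins)))  # cumsum by matmul

    def _knots(self, params: Tensor):
        K, B = self.K, self.B
        eps = 1e-3
        w = _softmax(params[:, :K]) * (1 - K * eps) + eps       # (n, K)
        h = _softmax(params[:, K:2 * K]) * (1 - K * eps) + eps
        widths = w * (2 * B)
        heights = h * (2 * B)
        cum_x = widths @ Tensor(self._cum) - B                   # right edges
        cum_y = heights @ Tensor(self._cum) - B
        n = params.shape[0]
        left = Tensor(np.full((n, 1), -B))
        x_edges = ad.concatenate([left, cum_x], axis=1)          # (n, K+1)
        y_edges = ad.concatenate([left, cum_y], axis=1)
        d_in = ad.softplus(params[:, 2 * K:] + _DERIV_SHIFT)     # (n, K-1)
        ones = Tensor(np.ones((n, 1)))
        derivs = ad.concatenate([ones, d_in, ones], axis=1)      # (n, K+1)
        return x_edges, y_edges, widths, heights, derivs

    def apply(self, x, params: Tensor) -> Tuple[Tensor, Tensor]:
        x = Tensor._lift(x)
        n = x.shape[0]
        K, B = self.K, self.B
        x_edges, y_edges, widths, heights, derivs = self._knots(params)

        xd = x.data
        inside = (np.abs(xd) < B)
        x_clip = np.clip(xd, -B, B * (1 - 1e-12))
        # bin index per row from detached knot positions
        internal = x_edges.data[:, 1:K]                          # (n, K-1)
        k = (x_clip[:, None] >= internal).sum(axis=1)            # (n,) in [0, K-1]
        mk = np.zeros((n, K)); mk[np.arange(n), k] = 1.0         # bin one-hot
        ml = np.zeros((n, K + 1)); ml[np.arange(n), k] = 1.0     # left knot
        mr = np.zeros((n, K + 1)); mr[np.arange(n), k + 1] = 1.0

        pick = lambda t, m: (t * Tensor(m)).sum(axis=1)
        x_k = pick(x_edges, ml)
        y_k = pick(y_edges, ml)
        w_k = pick(widths, mk)
        h_k = pick(heights, mk)
        d_k = pick(derivs, ml)
        d_k1 = pick(derivs, mr)

        ins = inside.astype(float)
        x_in = x * ins + Tensor(x_clip) * (1.0 - ins)  # keep grads inside only
        xi = (x_in - x_k) / w_k
        om = 1.0 - xi
        s = h_k / w_k
        den = s + (d_k1 + d_k - 2.0 * s) * xi * om
        z_in = y_k + h_k * (s * xi * xi + d_k * xi * om) / den
        deriv = s * s * (d_k1 * xi * xi + 2.0 * s * xi * om + d_k * om * om) \
            / (den * den)
        z = z_in * ins + x * (1.0 - ins)
        logdet = ad.log(deriv) * ins
        return z, logdet


class ConditionalFlow:
    """Stack of conditional 1-D invertible transforms with a shared conditioner.

    ``normalize`` (data -> latent) is analytic and differentiable in the
    conditioner parameters; ``transform`` exposes the latent -> data forward
    by monotone bisection.
    """

    def __init__(self, context_dim: int, hp: FlowHyperparams, seed_offset: int = 0):
        hp.validate()
        self.hp = hp
        self.context_dim = context_dim
        self.layers: List[object] = []
        for _ in range(hp.depth):
            if hp.family == "spline":
                self.layers.append(_RQSplineLayer(hp.n_bins, hp.bound))
            self.layers.append(_AffineLayer())
        self.n_params_total = sum(l.n_params for l in self.layers)
        rng = np.random.default_rng(hp.seed + seed_offset)
        # zero-initialised output => identity flow at initialisation
        self.conditioner = MLP(context_dim, hp.cond_hidden, self.n_params_total,
                               rng, zero_init_output=True)
        self._scaler: Optional[Tuple[np.ndarray, np.ndarray]] = None
        self.frozen = False
        self.history: List[dict] = []

    @property
    def parameters(self) -> List[Tensor]:
        return self.conditioner.parameters

    def freeze(self) -> "ConditionalFlow":
        for p in self.parameters:
            p.requires_grad = False
        self.frozen = True
        return self

    def fit_scaler(self, context: np.ndarray) -> None:
        mu = context.mean(0)
        sd = context.std(0)
        sd[sd < 1e-8] = 1.0
        self._scaler = (mu, sd)

    def _context(self, context: np.ndarray) -> Tensor:
        context = np.atleast_2d(np.asarray(context, float))
        if context.shape[1] != self.context_dim:
            raise InputError(
                f"context dim {context.shape[1]} != expected {self.context_dim}")
        if self._scaler is not None:
            mu, sd = self._scaler
            context = (context - mu) / sd
        return Tensor(context)

    def conditioner_params(self, context: np.ndarray) -> Tensor:
        return self.conditioner(self._context(context))

    def normalize(self, y, context, params: Optional[Tensor] = None
                  ) -> Tuple[Tensor, Tensor]:
        """Data -> latent with total log|dz/dy|."""
        if params is None:
            params = self.conditioner_params(context)
        x = Tensor._lift(y)
        logdet = Tensor(np.zeros(x.shape[0]))
        i = 0
        for layer in self.layers:
            p = params[:, i:i + layer.n_params]
            x, ld = layer.apply(x, p)
            logdet = logdet + ld
            i += layer.n_params
        return x, logdet

    def log_prob(self, y, context, params: Optional[Tensor] = None) -> Tensor:
        z, logdet = self.normalize(y, context, params)
        return -0.5 * (z * z) - 0.5 * LOG_2PI + logdet

    # -- generative direction ----------------------------------------------
    def forward(self, z: np.ndarray, context: np.ndarray,
                n_bisect: int = 70) -> Tuple[np.ndarray, np.ndarray]:
        """Latent -> data by bisection on the monotone normalize map.

        Returns (y, log|dy/dz|) with log|dy/dz| = -log|dz/dy| at the solution.
        """
        z = np.asarray(z, float).ravel()
        params = self.conditioner_params(context)
        params = Tensor(params.data)  # detach

        def g(y):
            return self.normalize(y, None, params=params)[0].data

        lo = np.full_like(z, -self.hp.bound - 1.0)
        hi = np.full_like(z, self.hp.bound + 1.0)
        for _ in range(60):  # expand brackets where needed
            bad_lo = g(lo) > z
            bad_hi = g(hi) < z
            if not bad_lo.any() and not bad_hi.any():
                break
            lo = np.where(bad_lo, lo * 2.0 - 1.0, lo)
            hi = np.where(bad_hi, hi * 2.0 + 1.0, hi)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            too_low = g(mid) < z
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        y = 0.5 * (lo + hi)
        _, ld = self.normalize(y, None, params=params)
        return y, -ld.data

    def transform(self, z, context, inverse: bool = False
                  ) -> Tuple[np.ndarray, np.ndarray]:
        """Invertible transform with log-determinant.

        forward (default): latent -> data.  ``inverse=True``: data -> latent.
        """
        if inverse:
            zt, ld = self.normalize(np.asarray(z, float).ravel(), context)
            return zt.data, ld.data
        return self.forward(z, context)


# -- training ------------------------------------------------------------------

def _context_stage1(phi: np.ndarray, a: np.ndarray) -> np.ndarray:
    onehot = np.stack([(a == HFNC).astype(float), (a == NIV).astype(float)], 1)
    return np.concatenate([phi, onehot], axis=1)


def _fit_flow(flow: ConditionalFlow, y_base: np.ndarray, context: np.ndarray,
              a: np.ndarray, y_strat: np.ndarray, hp: FlowHyperparams,
              dequantize: bool) -> ConditionalFlow:
    """Shared training loop: Adam on the conditioner, dequantization noise
    resampled per epoch, early stopping on fixed-noise validation NLL."""
    rng = np.random.default_rng(hp.seed + 7)
    if np.unique(y_strat).size > 4:  # continuous target: stratify by arm only
        y_strat = np.zeros(len(y_strat), dtype=int)
    tr, va = stratified_split(a, y_strat, hp.val_fraction, rng)
    flow.fit_scaler(context[tr])
    opt = Adam(flow.parameters, lr=hp.learning_rate,
               weight_decay=hp.weight_decay)

    def targets(idx, noise_rng):
        if dequantize:
            return y_base[idx] + noise_rng.uniform(size=idx.size)
        return y_base[idx]

    val_rng = np.random.default_rng(hp.seed + 101)
    y_val = targets(va, val_rng)
    ctx_val = context[va]

    best = (np.inf, get_params_vector(flow.parameters))
    stall = 0
    for epoch in range(hp.max_epochs):
        epoch_rng = np.random.default_rng(hp.seed + 1000 + epoch)
        y_tr = targets(tr, epoch_rng)
        ctx_tr = context[tr]
        for idx in minibatches(len(tr), hp.batch_size, epoch_rng):
            opt.zero_grad()
            lp = flow.log_prob(y_tr[idx], ctx_tr[idx])
            loss = -lp.mean()
            if not np.isfinite(loss.data):
                raise DivergenceError("non-finite flow loss", {"epoch": epoch})
            loss.backward()
            opt.step()
        val_nll = -float(flow.log_prob(y_val, ctx_val).mean().data)
        if hp.early_stop:
            monitored = val_nll
        else:  # converge on the training objective (MLE-style fits)
            monitored = -float(flow.log_prob(y_tr, ctx_tr).mean().data)
        flow.history.append({"epoch": epoch, "val_nll": val_nll,
                             "monitored": monitored, "lr": opt.lr})
        if monitored < best[0] - 1e-6:
            best = (monitored, get_params_vector(flow.parameters))
            stall = 0
        else:
            stall += 1
            # reduce-on-plateau: halve the step size and restart from the
            # best weights so minibatch noise does not freeze convergence
            if stall % 5 == 0:
                opt.lr *= 0.5
                set_params_vector(flow.parameters, best[1])
            if stall > hp.patience:
                break
    set_params_vector(flow.parameters, best[1])
    return flow


def fit_stage1(phi: np.ndarray, a: np.ndarray, y: np.ndarray,
               hp: FlowHyperparams, dequantize: bool = True) -> ConditionalFlow:
    """Fit the outcome flow p(y* | phi, a) by maximum likelihood."""
    phi = np.asarray(phi, float)
    context = _context_stage1(phi, a)
    flow = ConditionalFlow(context.shape[1], hp, seed_offset=11)
    return _fit_flow(flow, np.asarray(y, float), context, a, y, hp, dequantize)


def fit_stage2(stage1: ConditionalFlow, phi: np.ndarray, a: np.ndarray,
               y: np.ndarray, hp: FlowHyperparams,
               condition_on_treatment: bool = False,
               dequantize: bool = True) -> ConditionalFlow:
    """Fit the latent-adjustment flow with Stage 1 frozen.

    Composing stage-2 forward then stage-1 forward must maximise the
    likelihood of observed outcomes; with Stage 1 fixed this reduces to a
    density fit of the stage-1 latents ``z1 = g1(y*)`` under the stage-2
    flow, conditioned on ``phi`` only (the interventional latent must not
    depend on the received treatment; a treatment-conditioned variant exists
    for ablation).
    """
    if not stage1.frozen:
        raise TrainingError("Stage 1 must be frozen before fitting Stage 2")
    phi = np.asarray(phi, float)
    ctx1 = _context_stage1(phi, a)
    noise_rng = np.random.default_rng(hp.seed + 55)
    y_star = np.asarray(y, float)
    y_star = y_star + noise_rng.uniform(size=y_star.size) if dequantize else y_star
    z1 = stage1.normalize(y_star, ctx1)[0].data

    ctx2 = _context_stage1(phi, a) if condition_on_treatment else phi
    flow = ConditionalFlow(ctx2.shape[1] if ctx2.ndim > 1 else 1, hp,
                           seed_offset=23)
    flow.conditioned_on_treatment = condition_on_treatment
    return _fit_flow(flow, z1, ctx2, a, y, hp, dequantize=False)


def composed_log_prob(stage1: ConditionalFlow, stage2: ConditionalFlow,
                      y_star: np.ndarray, phi: np.ndarray, a: np.ndarray
                      ) -> np.ndarray:
    """log-density of y* under the composed stage-2 -> stage-1 flow."""
    ctx1 = _context_stage1(phi, a)
    z1, ld1 = stage1.normalize(y_star, ctx1)
    ctx2 = ctx1 if getattr(stage2, "conditioned_on_treatment", False) else phi
    lp2 = stage2.log_prob(z1.data, ctx2)
    return lp2.data + ld1.data


# -- the full model ------------------------------------------------------------

CATEGORY_NIV = "NIV_preferred"
CATEGORY_HFNC = "HFNC_preferred"
CATEGORY_INDIFFERENT = "indifferent"
ITE_INDIFFERENCE_BAND = 1e-3


def categorize(ite: float) -> str:
    """Three-way preference from the ITE sign beyond the +-0.001 band.

    ITE = P(IMV | NIV) - P(IMV | HFNC): negative favours NIV.  The
    indifferent band is closed: |ITE| <= 0.001.
    """
    if abs(ite) <= ITE_INDIFFERENCE_BAND:
        return CATEGORY_INDIFFERENT
    return CATEGORY_NIV if ite < 0 else CATEGORY_HFNC


class RepFlowCFR:
    """Stage-0 representation + Stage-1 outcome flow + Stage-2 adjustment flow."""

    def __init__(self, hp_cfr: Optional[CFRHyperparams] = None,
                 hp_flow: Optional[FlowHyperparams] = None,
                 condition_stage2_on_treatment: bool = False):
        self.hp_cfr = hp_cfr or CFRHyperparams()
        self.hp_flow = hp_flow or FlowHyperparams()
        self.condition_stage2_on_treatment = condition_stage2_on_treatment
        self.stage0: Optional[Stage0CFR] = None
        self.stage1: Optional[ConditionalFlow] = None
        self.stage2: Optional[ConditionalFlow] = None

    def fit(self, data: ModelInputs) -> "RepFlowCFR":
        self.stage0 = train_stage0(data, self.hp_cfr)
        phi = self.stage0.representations(data)
        self.stage1 = fit_stage1(phi, data.a, data.y, self.hp_flow).freeze()
        self.stage2 = fit_stage2(
            self.stage1, phi, data.a, data.y, self.hp_flow,
            condition_on_treatment=self.condition_stage2_on_treatment)
        return self

    def _require_fitted(self):
        if self.stage0 is None or self.stage1 is None or self.stage2 is None:
            raise TrainingError("model not fitted: call fit() first")

    def _event_thresholds(self, data: ModelInputs, a_code: int) -> np.ndarray:
        """Latent threshold t with event <=> u~ >= t, per encounter.

        By monotonicity of both flows, y* >= 1 <=> z1 >= g1(1 | phi, a)
        <=> u~ >= g2(g1(1 | phi, a) | phi).
        """
        phi = self.stage0.representations(data)
        n = phi.shape[0]
        ctx1 = _context_stage1(phi, np.full(n, a_code))
        z1_cut = self.stage1.normalize(np.ones(n), ctx1)[0].data
        ctx2 = (ctx1 if getattr(self.stage2, "conditioned_on_treatment", False)
                else phi)
        t = self.stage2.normalize(z1_cut, ctx2)[0].data
        return t

    def estimate_potential_outcomes(self, data: ModelInputs,
                                    n_samples: int = 100, seed: int = 0,
                                    method: str = "sample"
                                    ) -> Tuple[np.ndarray, np.ndarray]:
        """Outcome probabilities under each arm for every encounter.

        ``method='sample'`` draws ``n_samples`` latents per encounter, pushes
        them through stage 2 then stage 1 and averages the decoded events
        (implemented through the equivalent monotone threshold comparison).
        ``method='exact'`` is the infinite-sample limit ``1 - Phi(t)``.
        """
        self._require_fitted()
        if method == "sample" and n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        t_niv = self._event_thresholds(data, NIV)
        t_hfnc = self._event_thresholds(data, HFNC)
        if method == "exact":
            return norm.sf(t_niv), norm.sf(t_hfnc)
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((data.n, n_samples))  # shared draws per encounter
        p_niv = (u >= t_niv[:, None]).mean(axis=1)
        p_hfnc = (u >= t_hfnc[:, None]).mean(axis=1)
        return p_niv, p_hfnc

    def predict_ite(self, data: ModelInputs, n_samples: int = 100,
                    seed: int = 0, method: str = "sample") -> pd.DataFrame:
        p_niv, p_hfnc = self.estimate_potential_outcomes(
            data, n_samples=n_samples, seed=seed, method=method)
        return build_ite_results(data, p_niv, p_hfnc, n_samples, seed)

    def finetune(self, external: ModelInputs, fraction: float = 0.25,
                 max_epochs: Optional[int] = None
                 ) -> Tuple["RepFlowCFR", np.ndarray, np.ndarray]:
        """Continue optimisation of all stages on a seeded fraction of an
        external cohort; the remaining rows are reserved for evaluation."""
        from .cfr import finetune as finetune_stage0
        self._require_fitted()
        out = copy.deepcopy(self)
        out.stage0, tune_idx, eval_idx = finetune_stage0(
            self.stage0, external, fraction=fraction, hp=self.hp_cfr,
            max_epochs=max_epochs)
        if tune_idx.size and (max_epochs is None or max_epochs > 0):
            tune = external.subset(tune_idx)
            phi = out.stage0.representations(tune)
            hp = copy.deepcopy(out.hp_flow)
            if max_epochs is not None:
                hp.max_epochs = max_epochs
                hp.patience = min(hp.patience, max(1, max_epochs - 1))
            out.stage1 = fit_stage1(phi, tune.a, tune.y, hp).freeze()
            out.stage2 = fit_stage2(
                out.stage1, phi, tune.a, tune.y, hp,
                condition_on_treatment=out.condition_stage2_on_treatment)
        return out, tune_idx, eval_idx


def build_ite_results(data: ModelInputs, p_niv: np.ndarray, p_hfnc: np.ndarray,
                      n_samples: int, seed: int) -> pd.DataFrame:
    ite = p_niv - p_hfnc
    enc = (data.encounter_id if data.encounter_id is not None
           else np.arange(data.n))
    return pd.DataFrame({
        "encounter_id": enc,
        "p_niv": p_niv,
        "p_hfnc": p_hfnc,
        "ite": ite,
        "category": [categorize(v) for v in ite],
        "n_samples": n_samples,
        "seed": seed,
    })


def write_ite_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
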