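"""PGIN heads: context calibration, diagnostic decoding, entropy uncertainty
and the composite training objective.

The decoder maps the sampled latent path (optionally calibrated by static
context covariates) to per-timestep class probabilities; predictive
confidence is a temperature-scaled entropy normalized to [0, 1]; the full
objective combines weighted cross-entropy, the KL regularizer and a
temporal graph-smoothness penalty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Var, as_var, concat, softmax
from .pgin_core import kl_term

logger = logging.getLogger(__name__)

__all__ = [
    "HeadParams",
    "StepPrediction",
    "init_head_params",
    "calibrate",
    "decode",
    "uncertainty",
    "graph_smoothness",
    "cross_entropy",
    "pgin_loss",
]

_EPS = 1e-12  # probability floor before logarithms


@dataclass
class HeadParams:
    """Calibration, decoder and loss-weight parameters.

    ``cal_scale``/``cal_shift`` are (d_c, d) linear maps from context to a
    multiplicative (1 + g) scale and additive shift on the calibrated vector;
    ``dec_weight`` is ((d + d_c), |Y|).  ``tau_u`` is the entropy temperature
    (distinct from any windowing time constant); ``beta``/``rho`` weight the
    KL and graph-smoothness terms; ``class_weights`` handle imbalance.
    """

    cal_scale: Var
    cal_shift: Var
    dec_weight: Var
    dec_bias: Var
    tau_u: float = 1.0
    beta: float = 0.005
    rho: float = 0.05
    class_weights: np.ndarray | None = None
    calibrate_target: str = "latent"  # or "embedding"

    def __post_init__(self):
        if self.tau_u <= 0:
            raise ValueError("tau_u must be > 0")
        if self.beta < 0 or self.rho < 0:
            raise ValueError("beta and rho must be >= 0")
        if self.class_weights is not None and np.any(np.asarray(self.class_weights) <= 0):
            raise ValueError("class weights must be positive")

    def parameters(self) -> list[Var]:
        return [self.cal_scale, self.cal_shift, self.dec_weight, self.dec_bias]


@dataclass
class StepPrediction:
    """One timestep's class distribution and normalized uncertainty."""

    probs: np.ndarray  # (|Y|,) sums to 1
    u: float  # normalized entropy, in [0, 1/tau_u]


def init_head_params(
    d_in: int,
    n_classes: int,
    d_c: int = 0,
    seed: int = 0,
    tau_u: float = 1.0,
    beta: float = 0.005,
    rho: float = 0.05,
    class_weights: np.ndarray | None = None,
) -> HeadParams:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    lim = 1.0 / np.sqrt(max(d_in + d_c, 1))
    return HeadParams(
        cal_scale=Var(np.zeros((max(d_c, 1), d_in)), name="cal_scale"),
        cal_shift=Var(np.zeros((max(d_c, 1), d_in)), name="cal_shift"),
        dec_weight=Var(rng.uniform(-lim, lim, (d_in + d_c, n_classes)), name="dec_weight"),
        dec_bias=Var(np.zeros(n_classes), name="dec_bias"),
        tau_u=tau_u,
        beta=beta,
        rho=rho,
        class_weights=class_weights,
    )


def _wrap(x):
    return x if isinstance(x, Var) else as_var(x)


def _ret(out, *inputs):
    if any(isinstance(x, Var) for x in inputs):
        return out
    return out.value


def calibrate(h, c, params: HeadParams):
    """Context-modulated affine recalibration h̃ = (1 + g_scale(c)) ⊙ h + g_shift(c).

    With empty or absent context the map is the identity, as is a
    zero-initialized calibration network.
    """
    hv = _wrap(h)
    if c is None or np.size(np.asarray(c if not isinstance(c, Var) else c.value)) == 0:
        return _ret(hv * 1.0, h)
    cv = _wrap(c)
    scale = cv @ params.cal_scale
    shift = cv @ params.cal_shift
    return _ret((1.0 + scale) * hv + shift, h, c)


def decode(z_t, c_t, params: HeadParams):
    """Decoding head ŷ = softmax(W_y [ẑ, c] + b_y); a valid probability vector."""
    zv = _wrap(z_t)
    if c_t is not None and np.size(np.asarray(c_t if not isinstance(c_t, Var) else c_t.value)):
        zv = concat([zv, _wrap(c_t)], axis=-1)
    logits = zv @ params.dec_weight + params.dec_bias
    return _ret(softmax(logits, axis=-1), z_t, c_t)


def uncertainty(y_hat, tau_u: float = 1.0, normalized: bool = True):
    """Temperature-scaled entropy confidence score.

    U = [−Σ_j ŷ_j ln ŷ_j] / (τ_u · ln |Y|) with the 0·ln 0 ≡ 0 convention;
    at τ_u = 1 the normalized score lies in [0, 1] (0 = one-hot,
    1 = uniform).  ``normalized=False`` returns raw entropy / τ_u.
    """
    if tau_u <= 0:
        raise ValueError("tau_u must be > 0")
    yv = _wrap(y_hat)
    p = yv.value
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("y_hat is not a valid probability simplex")
    n_classes = p.shape[-1]
    ent = -(yv * yv.clip_min(_EPS).log()).sum(axis=-1)
    denom = tau_u * (np.log(n_classes) if normalized else 1.0)
    return _ret(ent * (1.0 / denom), y_hat)


def graph_smoothness(A_path):
    """Temporal smoothness penalty Σ_{t≥2} ‖A_t − A_{t−1}‖_F² on the adjacency
    sequence (time on the second-to-rightmost-but-two axis: (..., T, K, K))."""
    Av = _wrap(A_path)
    T = Av.shape[-3]
    if T < 2:
        warnings.warn("graph_smoothness needs T >= 2; returning 0", stacklevel=2)
        return _ret(as_var(0.0) * 1.0, A_path)
    diff = Av[..., 1:, :, :] - Av[..., :-1, :, :]
    return _ret((diff * diff).sum(), A_path)


def cross_entropy(probs, labels: np.ndarray, class_weights: np.ndarray | None = None):
    """Mean (optionally class-weighted) cross-entropy of probability outputs.

    ``probs`` has classes on the last axis; ``labels`` are integer class
    indices matching the leading shape.  Probabilities are floored at 1e-12
    before the logarithm.
    """
    pv = _wrap(probs)
    labels = np.asarray(labels, dtype=int)
    n_classes = pv.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"label outside [0, {n_classes}): {labels.min()}..{labels.max()}")
    onehot = np.eye(n_classes)[labels]
    logp = pv.clip_min(_EPS).log()
    nll = -(logp * onehot).sum(axis=-1)
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=float)[labels]
        out = (nll * w).sum() * (1.0 / w.sum())
    else:
        out = nll.mean()
    return _ret(out, probs)


def pgin_loss(
    probs,
    labels: np.ndarray,
    mu,
    logvar,
    A_path,
    params: HeadParams,
    prior_mode: str = "standard",
    prior_mean=None,
):
    """Composite PGIN objective and its component breakdown.

    total = mean_t wCE(ŷ(t), y(t)) + β·L_KL + ρ·smoothness.  Window-level
    labels are broadcast over the timestep axis of ``probs``.  Returns
    ``(total, components)`` where components is a dict of the unweighted
    terms (as Vars when inputs are Vars).
    """
    pv = _wrap(probs)
    labels = np.asarray(labels, dtype=int)
    if labels.ndim == pv.ndim - 2:  # one label per window -> broadcast over time
        labels = np.broadcast_to(labels[..., None], pv.shape[:-1])
    ce = cross_entropy(pv, labels, params.class_weights)
    kl = kl_term(_wrap(mu), _wrap(logvar), prior_mode, prior_mean)
    # average KL and smoothness over windows so weights are batch-size free
    n_windows = int(np.prod(pv.shape[:-2])) if pv.ndim > 2 else 1
    kl = kl * (1.0 / n_windows)
    sm = graph_smoothness(_wrap(A_path)) * (1.0 / n_windows)
    total = ce + params.beta * kl + params.rho * sm
    components = {"ce": ce, "kl": kl, "smoothness": sm}
    if any(isinstance(x, Var) for x in (probs, mu, logvar, A_path)):
        return total, components
    return float(total.value), {k: float(v.value) for k, v in components.items()}
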