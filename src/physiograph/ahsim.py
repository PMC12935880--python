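"""Adaptive Health State Inference Mechanism (AHSIM).

A post-representation inference layer over the PGIN latent path: a gated
recursive evidence state s(t) accumulates per-timestep class beliefs at a
rate driven by uncertainty and latent change; temporal attention pools the
evidence into an aggregate S_agg; a risk-gated softmax combines evidence,
per-class aggregate uncertainty and medical risk priors into the final
distribution π; an entropy-regularized trust gate penalizes timesteps whose
instantaneous beliefs disagree with the aggregate; fine-class probability
mass is coarsened through a fixed hierarchy map; and an adaptive threshold
decides between emitting the argmax label and deferring to a human.

Notation notes (symbol collisions resolved by field names): the hierarchy
map is ``hierarchy`` (not the distribution π); the uncertainty weight in the
gate is ``lambda_u``; the loss weights are ``lambda_trust``/``lambda_hier``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Var, as_var, concat, softmax, stack

__all__ = [
    "AhsimParams",
    "DiagnosticTrace",
    "init_ahsim_params",
    "update_state",
    "aggregate",
    "gate_decision",
    "trust_loss",
    "coarsen",
    "adaptive_threshold",
    "emit_or_defer",
    "ahsim_loss",
    "ahsim_forward",
]

_EPS = 1e-12


def _wrap(x):
    return x if isinstance(x, Var) else as_var(x)


def _ret(out, *inputs):
    if any(isinstance(x, Var) for x in inputs):
        return out
    if isinstance(out, tuple):
        return tuple(o.value if isinstance(o, Var) else o for o in out)
    return out.value


@dataclass
class AhsimParams:
    """Learnable weights and fixed settings of the adaptive inference layer.

    ``proj_weight (d_z, |Y|)``/``proj_bias`` project the latent state to
    instantaneous class evidence; ``gate_weight (2,)``/``gate_bias`` gate the
    update rate from [U(t), δ(t)]; ``attn_v (d_a)``, ``attn_weight
    (d_z + d_c, d_a)``, ``attn_bias`` score temporal salience;
    ``gamma``/``lambda_u``/``nu`` weight evidence, uncertainty and the risk
    priors ``risk_priors (|Y|)`` in the decision gate; ``trust_weight
    (d_z,)``/``trust_bias`` form the scalar trust gate; ``hierarchy`` maps
    fine class -> coarse class; ``theta0``/``eps_theta``/``zeta`` set the
    adaptive threshold; ``s0`` is the initial evidence simplex.
    """

    proj_weight: Var
    proj_bias: Var
    gate_weight: Var
    gate_bias: Var
    attn_v: Var
    attn_weight: Var
    attn_bias: Var
    trust_weight: Var
    trust_bias: Var
    gamma: float = 1.0
    lambda_u: float = 1.0
    nu: float = 0.0
    risk_priors: np.ndarray = field(default_factory=lambda: np.zeros(2))
    hierarchy: dict = field(default_factory=dict)  # fine class -> coarse class
    theta0: float = 0.5
    eps_theta: float = 0.1
    zeta: float = 0.0
    lambda_trust: float = 0.1
    lambda_hier: float = 0.5
    s0: np.ndarray | None = None
    uagg_mode: str = "per_class"  # or "scalar" (provably vacuous in the gate)

    def __post_init__(self):
        if not (0.0 <= self.theta0 <= 1.0):
            raise ValueError("theta0 must be in [0, 1]")
        if self.s0 is not None:
            s0 = np.asarray(self.s0, dtype=float)
            if np.any(s0 < 0) or abs(s0.sum() - 1.0) > 1e-6:
                raise ValueError("s0 must be a probability vector")
        if self.hierarchy:
            coarse = set(self.hierarchy.values())
            if set(range(len(self.hierarchy))) != set(self.hierarchy.keys()):
                raise ValueError("hierarchy must be total over fine classes 0..|Y|-1")
            if set(range(len(coarse))) != coarse:
                raise ValueError("coarse classes must be 0..n_coarse-1 (surjective)")

    def parameters(self) -> list[Var]:
        return [
            self.proj_weight,
            self.proj_bias,
            self.gate_weight,
            self.gate_bias,
            self.attn_v,
            self.attn_weight,
            self.attn_bias,
            self.trust_weight,
            self.trust_bias,
        ]


@dataclass
class DiagnosticTrace:
    """Per-window record of the adaptive inference pass (detached arrays)."""

    s: np.ndarray  # (T, |Y|) evidence states
    alpha: np.ndarray  # (T,) gate values
    delta: np.ndarray  # (T,) latent-change norms
    eta: np.ndarray  # (T,) attention weights, sum 1
    S_agg: np.ndarray  # (|Y|,)
    pi: np.ndarray  # (|Y|,) gated distribution
    y_final: int
    y_coarse: np.ndarray | None  # coarse distribution
    U: np.ndarray  # (T,) per-step uncertainty
    U_agg: np.ndarray  # (|Y|,) per-class aggregate uncertainty
    theta: np.ndarray  # (T,) thresholds
    step_decisions: list  # per step: ("emit", class) | ("defer", None)
    decision: tuple  # aggregate decision


def init_ahsim_params(
    d_z: int,
    n_classes: int,
    d_c: int = 0,
    d_a: int = 8,
    seed: int = 0,
    hierarchy: dict | None = None,
    risk_priors: np.ndarray | None = None,
    theta0: float = 0.5,
    eps_theta: float = 0.1,
    zeta: float = 0.0,
    gamma: float = 4.0,
    lambda_u: float = 1.0,
    nu: float = 0.0,
    lambda_trust: float = 0.1,
    lambda_hier: float = 0.5,
) -> AhsimParams:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    lim = 1.0 / np.sqrt(d_z)
    if hierarchy is None:
        hierarchy = {j: j for j in range(n_classes)}  # identity hierarchy
    if risk_priors is None:
        risk_priors = np.zeros(n_classes)
    return AhsimParams(
        proj_weight=Var(rng.uniform(-lim, lim, (d_z, n_classes)), name="proj_weight"),
        proj_bias=Var(np.zeros(n_classes), name="proj_bias"),
        gate_weight=Var(np.array([1.0, 1.0]), name="gate_weight"),
        gate_bias=Var(np.zeros(1), name="gate_bias"),
        attn_v=Var(rng.uniform(-1 / np.sqrt(d_a), 1 / np.sqrt(d_a), d_a), name="attn_v"),
        attn_weight=Var(rng.uniform(-lim, lim, (d_z + d_c, d_a)), name="attn_weight"),
        attn_bias=Var(np.zeros(d_a), name="attn_bias"),
        trust_weight=Var(rng.uniform(-lim, lim, d_z), name="trust_weight"),
        trust_bias=Var(np.zeros(1), name="trust_bias"),
        gamma=gamma,
        lambda_u=lambda_u,
        nu=nu,
        risk_priors=np.asarray(risk_priors, dtype=float),
        hierarchy=dict(hierarchy),
        theta0=theta0,
        eps_theta=eps_theta,
        zeta=zeta,
        lambda_trust=lambda_trust,
        lambda_hier=lambda_hier,
        s0=np.full(n_classes, 1.0 / n_classes),
    )


# ---------------------------------------------------------------------------
# single-step / single-window operations
# ---------------------------------------------------------------------------


def update_state(s_prev, z_t, u_t, delta_t, params: AhsimParams):
    """Gated recursive evidence update.

    α_t = sigmoid(W_α [U_t, δ_t] + b_α);
    s_t = (1 − α_t)·s_{t−1} + α_t·softmax(W_s ẑ_t + b_s).
    Convexity keeps s_t on the simplex whenever s_prev is.
    """
    sv, zv = _wrap(s_prev), _wrap(z_t)
    uv, dv = _wrap(u_t), _wrap(delta_t)
    feats = stack([uv, dv], axis=-1)  # (..., 2)
    alpha = ((feats * params.gate_weight).sum(axis=-1) + params.gate_bias[0]).sigmoid()
    inst = softmax(zv @ params.proj_weight + params.proj_bias, axis=-1)
    a = alpha.reshape(*alpha.shape, 1) if alpha.ndim else alpha
    s_t = (1.0 - a) * sv + a * inst
    return _ret((s_t, alpha), s_prev, z_t, u_t, delta_t)


def aggregate(s_path, z_path, c_path, params: AhsimParams):
    """Attention-weighted pooling of the evidence path.

    η = softmax_t(vᵀ tanh(W_η [ẑ_t, c_t] + b_η)); S_agg = Σ_t η(t) s(t).
    """
    sv, zv = _wrap(s_path), _wrap(z_path)
    if sv.shape[-2] != zv.shape[-2]:
        raise ValueError("s_path and z_path must share the time axis")
    x = zv
    if c_path is not None and np.size(np.asarray(c_path if not isinstance(c_path, Var) else c_path.value)):
        x = concat([zv, _wrap(c_path)], axis=-1)
    scores = (x @ params.attn_weight + params.attn_bias).tanh() @ params.attn_v  # (..., T)
    eta = softmax(scores, axis=-1)
    S_agg = (eta.reshape(*eta.shape, 1) * sv).sum(axis=-2)
    return _ret((S_agg, eta), s_path, z_path, c_path)


def gate_decision(S_agg, U_agg, params: AhsimParams):
    """Risk-gated decision distribution and final label.

    π_j ∝ exp(γ·S_agg[j] − λ_u·U_agg[j] + ν·m_j); ŷ_final = argmax_j π_j
    (ties to the lowest index).  A scalar (class-constant) U_agg cancels in
    the softmax, which is why the per-class aggregate is the default.
    """
    Sv, Uv = _wrap(S_agg), _wrap(U_agg)
    if params.uagg_mode == "scalar":
        Uv = as_var(np.broadcast_to(np.mean(Uv.value, axis=-1, keepdims=True), Sv.shape).copy())
    logits = params.gamma * Sv - params.lambda_u * Uv + params.nu * as_var(params.risk_priors)
    pi = softmax(logits, axis=-1)
    y_final = np.argmax(pi.value, axis=-1)  # np.argmax takes lowest index on ties
    out = _ret(pi, S_agg, U_agg)
    return out, y_final


def trust_loss(z_path, step_probs, pi, params: AhsimParams):
    """Entropy-regularized trust gate loss.

    T(t) = sigmoid(w_Tᵀ ẑ_t + b_T); L_trust = mean_t T(t)·KL(ŷ(t) ‖ π).
    The KL is computed against the gated distribution π (the argmax label
    would be ill-typed inside a divergence); probabilities are floored at
    1e-12.
    """
    zv, yv, piv = _wrap(z_path), _wrap(step_probs), _wrap(pi)
    gate = ((zv * params.trust_weight).sum(axis=-1) + params.trust_bias[0]).sigmoid()  # (..., T)
    logy = yv.clip_min(_EPS).log()
    lead = piv.shape[:-1]
    logpi = piv.clip_min(_EPS).log().reshape(*lead, 1, piv.shape[-1])
    kl = (yv * (logy - logpi)).sum(axis=-1)  # (..., T)
    out = (gate * kl).mean(axis=-1)
    if out.ndim:
        out = out.mean()
    return _ret(out, z_path, step_probs, pi)


def coarsen(pi, hierarchy: dict):
    """Sum fine-class probability mass into coarse classes via the hierarchy map."""
    piv = _wrap(pi)
    n_fine = piv.shape[-1]
    missing = [j for j in range(n_fine) if j not in hierarchy]
    if missing:
        raise ValueError(f"fine classes without a coarse parent: {missing}")
    n_coarse = max(hierarchy.values()) + 1
    M = np.zeros((n_fine, n_coarse))
    for f, c in hierarchy.items():
        M[f, c] = 1.0
    return _ret(piv @ as_var(M), pi)


def adaptive_threshold(u_t, z_t, params: AhsimParams):
    """Adaptive decision threshold θ_t = clip(θ₀ + ε_θ·U_t + ζ·Var(ẑ_t), 0, 1).

    Var is the across-dimension variance of the latent vector at t.
    """
    u = np.asarray(u_t if not isinstance(u_t, Var) else u_t.value, dtype=float)
    z = np.asarray(z_t if not isinstance(z_t, Var) else z_t.value, dtype=float)
    var = z.var(axis=-1) if z.ndim else 0.0
    theta = params.theta0 + params.eps_theta * u + params.zeta * var
    return np.clip(theta, 0.0, 1.0)


def emit_or_defer(pi, theta_t: float):
    """Selective prediction: emit the argmax class if max_j π_j ≥ θ_t, else defer."""
    p = np.asarray(pi if not isinstance(pi, Var) else pi.value, dtype=float)
    if p.max() >= theta_t:
        return ("emit", int(np.argmax(p)))
    return ("defer", None)


def ahsim_loss(
    pi,
    label,
    l_trust,
    y_coarse,
    coarse_label,
    lambda_trust: float,
    lambda_hier: float,
):
    """Composite adaptive-inference objective.

    total = CE(π, y) + λ₁·L_trust + λ₂·CE(ŷ_coarse, y_coarse), with the CE
    computed on the distributions (differentiable; the argmax enters only the
    emitted decision).  Returns (total, components).
    """
    from .pgin_heads import cross_entropy

    piv = _wrap(pi)
    ce = cross_entropy(piv, np.asarray(label))
    lt = _wrap(l_trust)
    components = {"ce": ce, "trust": lt}
    total = ce + lambda_trust * lt
    if y_coarse is not None and coarse_label is not None:
        ch = cross_entropy(_wrap(y_coarse), np.asarray(coarse_label))
        components["hier"] = ch
        total = total + lambda_hier * ch
    if any(isinstance(x, Var) for x in (pi, l_trust, y_coarse)):
        return total, components
    return float(total.value), {k: float(v.value) for k, v in components.items()}


# ---------------------------------------------------------------------------
# full pass over a window batch
# ---------------------------------------------------------------------------


def ahsim_forward(
    z_path,
    step_probs,
    step_u,
    c_path=None,
    params: AhsimParams | None = None,
) -> dict:
    """Run the adaptive inference layer over (N, T, ·) latent paths.

    Parameters
    ----------
    z_path:
        (N, T, d_z) sampled latent paths (Var or array).
    step_probs:
        (N, T, |Y|) per-step class probabilities from the PGIN decoder.
    step_u:
        (N, T) per-step normalized uncertainties.

    Returns a dict of Vars: evidence path ``s``, gates ``alpha``, change
    norms ``delta``, attention ``eta``, aggregates ``S_agg``, ``U_agg``,
    gated distribution ``pi``, trust loss ``l_trust`` and the numpy
    ``y_final``.
    """
    assert params is not None
    zv, yv, uv = _wrap(z_path), _wrap(step_probs), _wrap(step_u)
    N, T, n_classes = yv.shape
    # rate of latent change delta(t) = ||z(t) - z(t-1)||, delta(1) = 0
    dz = zv[:, 1:, :] - zv[:, :-1, :]
    # smoothed norm, exactly 0 at zero change, finite gradient at the origin
    norms = ((dz * dz).sum(axis=-1) + _EPS).sqrt() - np.sqrt(_EPS)
    delta = concat([as_var(np.zeros((N, 1))), norms], axis=-1)
    s0 = params.s0 if params.s0 is not None else np.full(n_classes, 1.0 / n_classes)
    s_prev = as_var(np.broadcast_to(s0, (N, n_classes)).copy())
    s_list: list[Var] = []
    alpha_list: list[Var] = []
    for t in range(T):
        s_prev, alpha_t = update_state(
            s_prev, zv[:, t, :], uv[:, t], delta[:, t], params
        )
        s_list.append(s_prev)
        alpha_list.append(alpha_t)
    s = stack(s_list, axis=1)  # (N, T, |Y|)
    alpha = stack(alpha_list, axis=1)
    S_agg, eta = aggregate(s, zv, c_path, params)
    # per-class aggregate uncertainty: across-time sd of each class probability
    mean_p = yv.mean(axis=1)  # (N, |Y|)
    centered = yv - mean_p.reshape(N, 1, n_classes)
    U_agg = ((centered * centered).mean(axis=1) + _EPS).sqrt()
    pi, y_final = gate_decision(S_agg, U_agg, params)
    l_trust = trust_loss(zv, yv, pi, params)
    return {
        "s": s,
        "alpha": alpha,
        "delta": delta,
        "eta": eta,
        "S_agg": S_agg,
        "U_agg": U_agg,
        "pi": pi,
        "l_trust": l_trust,
        "y_final": y_final,
    }


def diagnostic_trace(
    z_path: np.ndarray,
    step_probs: np.ndarray,
    step_u: np.ndarray,
    params: AhsimParams,
    c_path: np.ndarray | None = None,
) -> DiagnosticTrace:
    """Full per-window diagnostic record, including thresholds and decisions."""
    out = ahsim_forward(z_path[None], step_probs[None], step_u[None], None if c_path is None else c_path[None], params)
    pi = out["pi"].value[0]
    theta = np.array(
        [adaptive_threshold(step_u[t], z_path[t], params) for t in range(len(step_u))]
    )
    step_decisions = [emit_or_defer(pi, th) for th in theta]
    agg_decision = emit_or_defer(pi, float(theta.mean()))
    y_coarse = coarsen(pi, params.hierarchy) if params.hierarchy else None
    return DiagnosticTrace(
        s=out["s"].value[0],
        alpha=out["alpha"].value[0],
        delta=out["delta"].value[0],
        eta=out["eta"].value[0],
        S_agg=out["S_agg"].value[0],
        pi=pi,
        y_final=int(out["y_final"][0]),
        y_coarse=y_coarse,
        U=np.asarray(step_u, dtype=float),
        U_agg=out["U_agg"].value[0],
        theta=theta,
        step_decisions=step_decisions,
        decision=agg_decision,
    )
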