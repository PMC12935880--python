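"""PGIN core: sensor encoders, dynamic symmetric adjacency, graph propagation
and the variational latent-state model.

The PhysioGraph Inference Network (PGIN) treats the K sensor channels as
nodes of a time-varying graph.  At every timestep the channels are embedded
by per-sensor affine encoders, pairwise edge scores produce a symmetric
stochastic-mass adjacency, one graph-convolution layer propagates
information across sensors, and the pooled embedding sequence drives a
bidirectional recurrent variational posterior over a continuous latent
health-state path z(1:T), sampled via the reparameterization trick.

All operations accept either plain ``ndarray`` inputs (returning arrays) or
:class:`~physiograph.autodiff.Var` nodes (returning differentiable nodes).
Functional single-timestep forms mirror the model equations; the batched
:func:`pgin_forward` runs the whole stack over (N, K, L) window batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Var, as_var, softmax, stack

__all__ = [
    "PginParams",
    "LatentTrace",
    "init_pgin_params",
    "encode_sensors",
    "soft_sym",
    "build_adjacency",
    "propagate",
    "mean_pool",
    "posterior",
    "sample_path",
    "kl_term",
    "pgin_forward",
    "latent_trace",
]


def _wrap(x):
    return x if isinstance(x, Var) else as_var(x)


def _ret(out, *inputs):
    """Return plain arrays when no input carried gradient tape."""
    if any(isinstance(x, Var) for x in inputs):
        return out
    if isinstance(out, tuple):
        return tuple(o.value if isinstance(o, Var) else o for o in out)
    return out.value


def _activate(x: Var, tag: str) -> Var:
    if tag == "relu":
        return x.relu()
    if tag == "tanh":
        return x.tanh()
    if tag == "identity":
        return x
    raise ValueError(f"unknown activation '{tag}'")


@dataclass
class PginParams:
    """All learnable weights and structural hyperparameters of the PGIN core.

    Shapes (d_k = per-sensor input dimension, 1 for univariate channels):
    ``encoder_weight (K, d_h, d_k)``, ``encoder_bias (K, d_h)``; edge kernel
    either a similarity projection ``edge_proj (d_h, d_h)`` or a shared
    one-hidden-layer scorer (``edge_w1/edge_w2 (d_h, d_h)``, ``edge_b (d_h)``,
    ``edge_v (d_h)``); propagation ``gcn_weight (d_h, d_g)``, ``gcn_bias``;
    latent transition ``trans_weight (d_z + d_g, d_z)``, ``trans_bias``;
    posterior BiRNN weights and the linear heads to (μ, log σ²).
    """

    encoder_weight: Var
    encoder_bias: Var
    edge_proj: Var
    edge_w1: Var
    edge_w2: Var
    edge_b: Var
    edge_v: Var
    gcn_weight: Var
    gcn_bias: Var
    trans_weight: Var
    trans_bias: Var
    rnn_w_in_f: Var
    rnn_w_hh_f: Var
    rnn_b_f: Var
    rnn_w_in_b: Var
    rnn_w_hh_b: Var
    rnn_b_b: Var
    mu_weight: Var
    mu_bias: Var
    logvar_weight: Var
    logvar_bias: Var
    d_h: int = 8
    d_g: int = 8
    d_z: int = 8
    d_r: int = 16
    frame_stride: int = 4  # hop between successive per-sensor frames
    activation: str = "relu"
    edge_kernel: str = "similarity"  # or "mlp"
    adjacency_mode: str = "rowwise"  # or "global"
    bidirectional: bool = True

    def parameters(self) -> list[Var]:
        out = [
            self.encoder_weight,
            self.encoder_bias,
            self.gcn_weight,
            self.gcn_bias,
            self.trans_weight,
            self.trans_bias,
            self.rnn_w_in_f,
            self.rnn_w_hh_f,
            self.rnn_b_f,
            self.mu_weight,
            self.mu_bias,
            self.logvar_weight,
            self.logvar_bias,
        ]
        if self.edge_kernel == "similarity":
            out.append(self.edge_proj)
        else:
            out += [self.edge_w1, self.edge_w2, self.edge_b, self.edge_v]
        if self.bidirectional:
            out += [self.rnn_w_in_b, self.rnn_w_hh_b, self.rnn_b_b]
        return out


@dataclass
class LatentTrace:
    """Per-window diagnostic record of the PGIN forward pass (detached)."""

    H: np.ndarray  # (T, K, d_h) node embeddings
    A: np.ndarray  # (T, K, K) adjacency sequence
    H_prop: np.ndarray  # (T, K, d_g) propagated embeddings
    h_bar: np.ndarray  # (T, d_g) pooled embeddings
    mu: np.ndarray  # (T, d_z)
    logvar: np.ndarray  # (T, d_z)
    z_hat: np.ndarray  # (T, d_z) sampled path
    prior_mean: np.ndarray | None = None  # (T, d_z) when learned prior enabled


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    lim = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-lim, lim, shape)


def init_pgin_params(
    n_sensors: int,
    d_k: int = 8,
    d_h: int = 8,
    d_g: int = 8,
    d_z: int = 8,
    d_r: int = 16,
    frame_stride: int = 4,
    seed: int = 0,
    activation: str = "relu",
    edge_kernel: str = "similarity",
    adjacency_mode: str = "rowwise",
    bidirectional: bool = True,
) -> PginParams:
    """Scaled-uniform fan-in initialization of every PGIN weight array.

    ``d_k`` is the per-sensor frame width: each model timestep consumes a
    short frame of ``d_k`` consecutive samples per channel (hop
    ``frame_stride``), so the encoders see local waveform shape rather than
    isolated samples.  The log-variance head bias starts at -2 so early
    latent samples are concentrated (sd ≈ 0.37) rather than unit-noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    K = n_sensors
    if d_h == d_k:
        # near-identity start: embeddings initially preserve the raw frame, so
        # edge similarity scores reflect inter-channel signal correlation (the
        # mutual-information view of the dependence kernel) from step one
        enc_w = np.broadcast_to(np.eye(d_h), (K, d_h, d_k)).copy()
        enc_w += 0.1 * _uniform(rng, (K, d_h, d_k), d_k)
    else:
        enc_w = _uniform(rng, (K, d_h, d_k), d_k)
    return PginParams(
        encoder_weight=Var(enc_w, name="encoder_weight"),
        encoder_bias=Var(np.zeros((K, d_h)), name="encoder_bias"),
        edge_proj=Var(
            np.eye(d_h) + 0.1 * _uniform(rng, (d_h, d_h), d_h), name="edge_proj"
        ),
        edge_w1=Var(_uniform(rng, (d_h, d_h), d_h), name="edge_w1"),
        edge_w2=Var(_uniform(rng, (d_h, d_h), d_h), name="edge_w2"),
        edge_b=Var(_uniform(rng, (d_h,), d_h), name="edge_b"),
        edge_v=Var(_uniform(rng, (d_h,), d_h), name="edge_v"),
        gcn_weight=Var(_uniform(rng, (d_h, d_g), d_h), name="gcn_weight"),
        gcn_bias=Var(np.zeros(d_g), name="gcn_bias"),
        trans_weight=Var(_uniform(rng, (d_z + d_g, d_z), d_z + d_g), name="trans_weight"),
        trans_bias=Var(np.zeros(d_z), name="trans_bias"),
        rnn_w_in_f=Var(_uniform(rng, (d_g, d_r), d_g), name="rnn_w_in_f"),
        rnn_w_hh_f=Var(_uniform(rng, (d_r, d_r), d_r), name="rnn_w_hh_f"),
        rnn_b_f=Var(np.zeros(d_r), name="rnn_b_f"),
        rnn_w_in_b=Var(_uniform(rng, (d_g, d_r), d_g), name="rnn_w_in_b"),
        rnn_w_hh_b=Var(_uniform(rng, (d_r, d_r), d_r), name="rnn_w_hh_b"),
        rnn_b_b=Var(np.zeros(d_r), name="rnn_b_b"),
        frame_stride=frame_stride,
        mu_weight=Var(_uniform(rng, (d_r, d_z), d_r), name="mu_weight"),
        mu_bias=Var(np.zeros(d_z), name="mu_bias"),
        logvar_weight=Var(_uniform(rng, (d_r, d_z), d_r), name="logvar_weight"),
        logvar_bias=Var(np.full(d_z, -2.0), name="logvar_bias"),
        d_h=d_h,
        d_g=d_g,
        d_z=d_z,
        d_r=d_r,
        activation=activation,
        edge_kernel=edge_kernel,
        adjacency_mode=adjacency_mode,
        bidirectional=bidirectional,
    )


# ---------------------------------------------------------------------------
# single-timestep operations (mirroring the model equations)
# ---------------------------------------------------------------------------


def encode_sensors(x_t, params: PginParams):
    """Per-sensor affine embedding h_k = σ(W_k x_k + b_k), stacked to (K, d_h).

    ``x_t`` is the timestep frame: shape (K,) for univariate channels or
    (K, d_k) in general.
    """
    xv = _wrap(x_t)
    x = xv.value
    K = params.encoder_weight.shape[0]
    if x.shape[0] != K:
        raise ValueError(f"expected {K} sensors, got {x.shape[0]}")
    d_k = params.encoder_weight.shape[2]
    if x.ndim == 1:
        if d_k != 1:
            raise ValueError(f"sensor inputs are scalar but encoder expects d_k={d_k}")
        xv = xv.reshape(K, 1)
    elif x.shape[1] != d_k:
        k_bad = 0
        raise ValueError(f"sensor {k_bad}: input dim {x.shape[1]} != encoder d_k {d_k}")
    # (K, d_h, d_k) @ (K, d_k, 1) -> (K, d_h)
    pre = (params.encoder_weight @ xv.reshape(K, d_k, 1)).reshape(K, -1) + params.encoder_bias
    return _ret(_activate(pre, params.activation), x_t)


def _edge_scores(H: Var, params: PginParams) -> Var:
    """Pairwise edge scores over the trailing (K, d_h) axes (any leading dims)."""
    if params.edge_kernel == "similarity":
        Hp = H @ params.edge_proj
        return (Hp @ Hp.swapaxes(-1, -2)) * (1.0 / np.sqrt(params.d_h))
    if params.edge_kernel == "mlp":
        a = H @ params.edge_w1  # (..., K, d_h)
        b = H @ params.edge_w2
        K = H.shape[-2]
        lead = H.shape[:-2]
        a_i = a.reshape(*lead, K, 1, params.d_h)
        b_j = b.reshape(*lead, 1, K, params.d_h)
        return (a_i + b_j + params.edge_b).tanh() @ params.edge_v
    raise ValueError(f"unknown edge kernel '{params.edge_kernel}'")


def soft_sym(scores, mode: str = "rowwise"):
    """Map raw pairwise scores to a symmetric stochastic-mass adjacency.

    Row-wise mode: S = softmax over rows, A = (S + Sᵀ)/2 — symmetric,
    entries in (0, 1), total mass K.  (The literal "half the sum of row-wise
    softmaxes of z and zᵀ" is not symmetric in general; symmetrizing the
    single row-softmax guarantees it.)  Global mode: softmax over all K²
    scores, then symmetrized — total mass 1.
    """
    sv = _wrap(scores)
    if mode == "rowwise":
        S = softmax(sv, axis=-1)
    elif mode == "global":
        lead = sv.shape[:-2]
        K = sv.shape[-1]
        S = softmax(sv.reshape(*lead, K * K), axis=-1).reshape(*lead, K, K)
    else:
        raise ValueError(f"unknown adjacency mode '{mode}'")
    A = (S + S.swapaxes(-1, -2)) * 0.5
    return _ret(A, scores)


def build_adjacency(H_t, params: PginParams):
    """Symmetric dynamic adjacency from pairwise embedding scores via
    :func:`soft_sym` of the edge-kernel score matrix."""
    Hv = _wrap(H_t)
    if Hv.shape[-2] < 2:
        raise ValueError("adjacency requires at least 2 sensors")
    A = soft_sym(_edge_scores(Hv, params), params.adjacency_mode)
    return _ret(A, H_t)


def propagate(A_t, H_t, params: PginParams):
    """One graph-convolution step: H̃ = σ(A H W_GCN + b_GCN)."""
    Av, Hv = _wrap(A_t), _wrap(H_t)
    if Av.shape[-1] != Hv.shape[-2]:
        raise ValueError(f"A columns {Av.shape[-1]} != H rows {Hv.shape[-2]}")
    out = _activate(Av @ Hv @ params.gcn_weight + params.gcn_bias, params.activation)
    return _ret(out, A_t, H_t)


def mean_pool(H_prop, masked: np.ndarray | None = None):
    """Average node embeddings over sensors, excluding masked channels."""
    Hv = _wrap(H_prop)
    if masked is None or not np.any(masked) or np.all(masked):
        # no mask info, nothing masked, or everything masked (bias images
        # only): plain average
        out = Hv.mean(axis=-2)
    else:
        keep = (~np.asarray(masked, dtype=bool)).astype(float)
        w = keep / keep.sum()
        out = (Hv * w[:, None]).sum(axis=-2)
    return _ret(out, H_prop)


def _rnn_direction(x: Var, W_in: Var, W_hh: Var, b: Var, reverse: bool) -> Var:
    """Vanilla tanh RNN over the time axis of (..., T, d_in); returns (..., T, d_r)."""
    T = x.shape[-2]
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = None
    outs: list[Var] = [None] * T  # type: ignore[list-item]
    for t in order:
        xt = x[..., t, :]
        pre = xt @ W_in + b
        if h is not None:
            pre = pre + h @ W_hh
        h = pre.tanh()
        outs[t] = h
    return stack(outs, axis=-2)


def posterior(h_bar_path, params: PginParams):
    """Variational posterior parameters (μ_t, log σ_t²) over pooled embeddings.

    A bidirectional tanh RNN (directions summed) encodes the pooled sequence;
    linear heads map each step's code to the Gaussian posterior parameters.
    A forward-only (streaming/causal) variant is selected by
    ``params.bidirectional = False``.
    """
    x = _wrap(h_bar_path)
    if x.shape[-2] < 1:
        raise ValueError("posterior needs at least one timestep")
    r = _rnn_direction(x, params.rnn_w_in_f, params.rnn_w_hh_f, params.rnn_b_f, reverse=False)
    if params.bidirectional:
        r = r + _rnn_direction(x, params.rnn_w_in_b, params.rnn_w_hh_b, params.rnn_b_b, reverse=True)
    mu = r @ params.mu_weight + params.mu_bias
    logvar = r @ params.logvar_weight + params.logvar_bias
    return _ret((mu, logvar), h_bar_path)


def sample_path(
    mu,
    logvar,
    seed: int | np.random.Generator = 0,
    params: PginParams | None = None,
    h_bar_path=None,
    sample: bool = True,
):
    """Reparameterized latent path ẑ_t = μ_t + exp(logvar_t / 2)·ε_t.

    When ``params`` and ``h_bar_path`` are given, also rolls the learned
    transition prior mean forward: prior_mean(t) = tanh(W_z [ẑ(t−1), h̄_t] + b_z)
    with ẑ(0) = 0.  ``sample=False`` returns the posterior mean path.
    """
    muv, lvv = _wrap(mu), _wrap(logvar)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample:
        eps = rng.standard_normal(muv.shape)
        z = muv + (lvv * 0.5).exp() * eps
    else:
        z = muv
    prior_mean = None
    if params is not None and h_bar_path is not None:
        hb = _wrap(h_bar_path)
        T = z.shape[-2]
        d_z = z.shape[-1]
        prev = as_var(np.zeros(z.shape[:-2] + (d_z,)))
        means: list[Var] = []
        from .autodiff import concat

        for t in range(T):
            inp = concat([prev, hb[..., t, :]], axis=-1)
            m = (inp @ params.trans_weight + params.trans_bias).tanh()
            means.append(m)
            prev = z[..., t, :]
        prior_mean = stack(means, axis=-2)
    out = (z, prior_mean) if prior_mean is not None else (z, None)
    if isinstance(mu, Var) or isinstance(logvar, Var):
        return out
    return (out[0].value, None if out[1] is None else out[1].value)


def kl_term(mu, logvar, prior_mode: str = "standard", prior_mean=None):
    """KL divergence of the diagonal-Gaussian posterior from its prior, summed
    over time and latent dimensions.

    ``standard``: prior N(0, I).  ``learned``: prior N(prior_mean(t), I) from
    the latent transition model.  Closed form per (t, d):
    ½((μ−m)² + σ² − 1 − log σ²).
    """
    muv, lvv = _wrap(mu), _wrap(logvar)
    if not (np.all(np.isfinite(muv.value)) and np.all(np.isfinite(lvv.value))):
        raise ValueError("non-finite posterior parameters")
    if prior_mode == "standard":
        diff = muv
    elif prior_mode == "learned":
        if prior_mean is None:
            raise ValueError("learned prior mode requires prior_mean")
        diff = muv - _wrap(prior_mean)
    else:
        raise ValueError(f"unknown prior mode '{prior_mode}'")
    kl = (diff * diff + lvv.exp() - 1.0 - lvv) * 0.5
    return _ret(kl.sum(), mu, logvar, prior_mean)


# ---------------------------------------------------------------------------
# batched forward
# ---------------------------------------------------------------------------


def frame_windows(windows: np.ndarray, d_k: int, stride: int) -> np.ndarray:
    """Slice (N, K, L) windows into per-sensor frames (N, T, K, d_k).

    T = (L − d_k) // stride + 1; trailing samples that do not fill a frame
    are dropped.  With d_k = 1, stride = 1 this reduces to per-sample input.
    """
    N, K, L = windows.shape
    if d_k > L:
        raise ValueError(f"frame width {d_k} exceeds window length {L}")
    sw = np.lib.stride_tricks.sliding_window_view(windows, d_k, axis=2)  # (N,K,L-d_k+1,d_k)
    return np.ascontiguousarray(np.swapaxes(sw[:, :, ::stride, :], 1, 2))


def pgin_forward(
    windows: np.ndarray,
    params: PginParams,
    masked: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample: bool = True,
    need_prior: bool = False,
) -> dict:
    """Run the PGIN stack over a window batch.

    Parameters
    ----------
    windows:
        (N, K, L) z-scored window array.
    masked:
        Optional (K,) boolean mask of dropped channels (excluded from pooling).
    sample:
        Draw a reparameterized latent path (training) or use the posterior
        mean (deterministic evaluation).

    Returns a dict of Vars: ``H`` (N,L,K,d_h), ``A`` (N,L,K,K), ``h_bar``
    (N,L,d_g), ``mu``/``logvar``/``z_hat`` (N,L,d_z) and optionally
    ``prior_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    N, K, L = windows.shape
    if masked is not None and np.any(masked):
        windows = windows.copy()
        windows[:, np.asarray(masked, dtype=bool), :] = 0.0
    frames = frame_windows(windows, params.encoder_weight.shape[2], params.frame_stride)
    N, T, K, d_k = frames.shape
    xv = as_var(frames)
    pre = (xv.reshape(N, T, K, 1, d_k) * params.encoder_weight).sum(axis=-1)
    H = _activate(pre + params.encoder_bias, params.activation)
    A = build_adjacency(H, params)
    Hp = propagate(A, H, params)
    h_bar = mean_pool(Hp, masked)
    mu, logvar = posterior(h_bar, params)
    z, prior_mean = sample_path(
        mu,
        logvar,
        rng,
        params if need_prior else None,
        h_bar if need_prior else None,
        sample=sample,
    )
    out = {"H": H, "A": A, "h_bar": h_bar, "mu": mu, "logvar": logvar, "z_hat": z}
    if prior_mean is not None:
        out["prior_mean"] = prior_mean
    return out


def latent_trace(
    window: np.ndarray,
    params: PginParams,
    masked: np.ndarray | None = None,
    seed: int = 0,
    sample: bool = False,
    need_prior: bool = False,
) -> LatentTrace:
    """Detached per-window record of the PGIN forward pass for inspection."""
    out = pgin_forward(
        window[None], params, masked=masked,
        rng=np.random.default_rng(seed), sample=sample, need_prior=need_prior,
    )
    return LatentTrace(
        H=out["H"].value[0],
        A=out["A"].value[0],
        H_prop=propagate(out["A"], out["H"], params).value[0],
        h_bar=out["h_bar"].value[0],
        mu=out["mu"].value[0],
        logvar=out["logvar"].value[0],
        z_hat=out["z_hat"].value[0],
        prior_mean=None if "prior_mean" not in out else out["prior_mean"].value[0],
    )
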