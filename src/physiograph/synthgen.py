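"""Synthetic multichannel biosignal generation.

The generator realizes the assumed data-generating process behind the
inference stack: a discrete latent health state :math:`z(t)` evolving as a
Markov chain, per-sensor emissions that are noisy state-conditioned waveform
templates, and time-varying inter-sensor coupling realized as a shared
latent driver added to coupled channel pairs.  It also implements the
preprocessing (resampling, sliding-window segmentation, per-window
z-scoring), augmentation and corruption (additive noise, channel masking)
protocols used by the training and robustness experiments.

States are frequency-coded by default in the experiment configurations:
each (state, sensor) template is ``base + amp * sin(2π f t + phase)`` with a
state-specific frequency band, so windows remain discriminable after
per-window z-scoring removes mean and scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SensorRecording",
    "WindowBatch",
    "AugmentConfig",
    "sample_latent_path",
    "template_trajectory",
    "emit_signals",
    "simulate_recording",
    "mi_kernel",
    "corrupt",
    "preprocess_and_window",
    "augment",
    "default_sim_config",
]

_SD_GUARD = 1e-8  # below this a channel is treated as constant and z-scored to 0


# ---------------------------------------------------------------------------
# configuration & containers
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration of the latent-state biosignal simulator.

    Parameters
    ----------
    n_sensors:
        Number of channels K (>= 2).
    n_states:
        Number of discrete latent health states (>= 2).
    transition_matrix:
        Row-stochastic state transition kernel, shape ``(n_states, n_states)``.
    emission_templates:
        Array ``(n_states, n_sensors, 3)`` of ``(base, freq_hz, amplitude)``
        waveform descriptors per (state, sensor).
    noise_sd:
        Per-sensor emission noise standard deviation (scalar broadcast or
        length-K array).
    coupling_edges:
        Sequence of ``(i, j, weight)`` sensor pairs sharing a latent driver,
        weight in [0, 1].
    sample_rate:
        Sampling rate in Hz.
    duration:
        Recording length in seconds.
    dwell_scale:
        Mean number of samples a state is held (geometric dwell) before the
        transition kernel is consulted again.  1 = per-sample stepping.
    seed:
        Seed for the generator's random stream.
    state_class_map:
        Optional map latent state -> class label; identity by default.
    phases:
        Optional per-sensor phase offsets (radians); randomized from the seed
        when omitted.
    driver_corr_time:
        Correlation time (seconds) of the shared Ornstein–Uhlenbeck driver
        behind coupled channel pairs.
    """

    n_sensors: int
    n_states: int
    transition_matrix: np.ndarray
    emission_templates: np.ndarray
    noise_sd: float | np.ndarray = 0.1
    coupling_edges: tuple = ()
    sample_rate: float = 32.0
    duration: float = 60.0
    dwell_scale: float = 1.0
    seed: int = 0
    state_class_map: np.ndarray | None = None
    phases: np.ndarray | None = None
    driver_corr_time: float = 0.3

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.emission_templates = np.asarray(self.emission_templates, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def validate(self) -> None:
        if self.n_sensors < 2:
            raise ValueError("n_sensors must be >= 2")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        T = self.transition_matrix
        if T.shape != (self.n_states, self.n_states):
            raise ValueError(
                f"transition_matrix shape {T.shape} != ({self.n_states}, {self.n_states})"
            )
        if np.any(T < 0):
            rows = np.where((T < 0).any(axis=1))[0]
            raise ValueError(f"transition_matrix has negative entries in row(s) {rows.tolist()}")
        rowsum = T.sum(axis=1)
        bad = np.where(np.abs(rowsum - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"transition_matrix row(s) {bad.tolist()} are not stochastic "
                f"(sums {rowsum[bad].tolist()})"
            )
        if self.emission_templates.shape[:2] != (self.n_states, self.n_sensors):
            raise ValueError(
                "emission_templates must cover every (state, sensor) pair: expected "
                f"({self.n_states}, {self.n_sensors}, 3), got {self.emission_templates.shape}"
            )
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")
        for edge in self.coupling_edges:
            i, j, w = edge
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"coupling weight {w} for edge ({i},{j}) outside [0,1]")
            if i == j or not (0 <= i < self.n_sensors and 0 <= j < self.n_sensors):
                raise ValueError(f"invalid coupling edge ({i},{j})")
        if self.dwell_scale < 1:
            raise ValueError("dwell_scale must be >= 1")


@dataclass
class SensorRecording:
    """A multichannel recording with optional labels and synthetic ground truth."""

    signals: np.ndarray  # (K, T)
    sample_rate: float
    channel_meta: list = field(default_factory=list)  # per-channel dicts
    labels: np.ndarray | None = None  # (T,) int class per sample
    context: np.ndarray | None = None  # (T, d_c)
    truth_states: np.ndarray | None = None  # (T,) int latent state
    truth_coupling: np.ndarray | None = None  # (K, K) symmetric, zero diagonal
    subject: str = "S0"

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite entries")
        K, T = self.signals.shape
        if self.labels is not None and len(self.labels) != T:
            raise ValueError(f"labels length {len(self.labels)} != T {T}")
        if not self.channel_meta:
            self.channel_meta = [
                {"name": f"ch{k}", "modality": "generic", "units": "a.u.", "masked": False}
                for k in range(K)
            ]
        if self.truth_coupling is not None:
            C = np.asarray(self.truth_coupling, dtype=float)
            if not np.allclose(C, C.T) or np.any(np.diag(C) != 0):
                raise ValueError("truth_coupling must be symmetric with zero diagonal")
            self.truth_coupling = C

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def masked_channels(self) -> np.ndarray:
        return np.array([bool(m.get("masked", False)) for m in self.channel_meta])


@dataclass
class WindowBatch:
    """Fixed-length segmented windows with provenance.

    ``intervals`` are 0-based half-open ``[start, start+L)`` sample index pairs
    into the (resampled) source recording.
    """

    windows: np.ndarray  # (N, K, L), z-scored per window & channel
    window_labels: np.ndarray | None  # (N,)
    context: np.ndarray | None  # (N, d_c)
    intervals: np.ndarray  # (N, 2)
    source_id: str = ""
    sample_rate: float = 100.0
    masked_channels: np.ndarray | None = None  # (K,) bool
    subjects: np.ndarray | None = None  # (N,) subject id per window

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_length(self) -> int:
        return self.windows.shape[2]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def sample_latent_path(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample a latent-state path of length ``cfg.n_samples``.

    The first state is uniform over states.  Each state is held for a
    geometric number of samples with mean ``cfg.dwell_scale`` before the
    transition kernel is consulted (``dwell_scale=1`` reduces to per-sample
    Markov stepping).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    T = cfg.n_samples
    states = np.empty(T, dtype=np.int64)
    z = int(rng.integers(cfg.n_states))
    t = 0
    p_consult = 1.0 / cfg.dwell_scale
    while t < T:
        dwell = int(rng.geometric(p_consult)) if cfg.dwell_scale > 1 else 1
        end = min(t + dwell, T)
        states[t:end] = z
        t = end
        z = int(rng.choice(cfg.n_states, p=cfg.transition_matrix[z]))
    return states


def _ou_driver(T: int, corr_samples: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Ornstein–Uhlenbeck path (discretized AR(1))."""
    a = np.exp(-1.0 / max(corr_samples, 1e-9))
    noise = rng.standard_normal(T) * np.sqrt(1 - a * a)
    d = np.empty(T)
    d[0] = rng.standard_normal()
    for t in range(1, T):
        d[t] = a * d[t - 1] + noise[t]
    return d


def template_trajectory(states: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Deterministic (noise- and coupling-free) part of the emission, shape (K, T).

    Oscillations are phase-continuous across state switches: the phase is the
    integral of the state-dependent instantaneous frequency, so transitions
    change the pitch of a channel without discontinuities.
    """
    states = np.asarray(states, dtype=np.int64)
    K = cfg.n_sensors
    phases = cfg.phases
    if phases is None:
        phases = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2])).uniform(
            0, 2 * np.pi, K
        )
    base = cfg.emission_templates[states, :, 0]  # (T, K)
    freq = cfg.emission_templates[states, :, 1]
    amp = cfg.emission_templates[states, :, 2]
    phase = 2 * np.pi * np.cumsum(freq / cfg.sample_rate, axis=0) + np.asarray(phases)[None, :]
    return (base + amp * np.sin(phase)).T


def emit_signals(
    states: np.ndarray, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SensorRecording:
    """Emit the K-channel observation matrix for a latent-state path.

    Each channel is its state-conditioned template evaluated along the path,
    plus a shared driver term for coupled pairs, plus i.i.d. Gaussian noise.
    """
    states = np.asarray(states, dtype=np.int64)
    if states.min() < 0 or states.max() >= cfg.n_states:
        raise ValueError(
            f"state labels outside template range [0, {cfg.n_states}): "
            f"[{states.min()}, {states.max()}]"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    T = len(states)
    K = cfg.n_sensors
    X = template_trajectory(states, cfg).copy()

    coupling = np.zeros((K, K))
    for i, j, w in cfg.coupling_edges:
        driver = _ou_driver(T, cfg.driver_corr_time * cfg.sample_rate, rng)
        X[i] += w * driver
        X[j] += w * driver
        coupling[i, j] = coupling[j, i] = max(coupling[i, j], w)

    sd = np.broadcast_to(np.asarray(cfg.noise_sd, dtype=float), (K,))
    if np.any(sd > 0):
        X = X + sd[:, None] * rng.standard_normal((K, T))

    class_map = (
        np.arange(cfg.n_states) if cfg.state_class_map is None else np.asarray(cfg.state_class_map)
    )
    labels = class_map[states]
    return SensorRecording(
        signals=X,
        sample_rate=cfg.sample_rate,
        labels=labels,
        truth_states=states,
        truth_coupling=coupling,
    )


def simulate_recording(cfg: SimConfig, subject: str = "S0") -> SensorRecording:
    """Sample a latent path and emit the corresponding recording."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    states = sample_latent_path(cfg, rng)
    rec = emit_signals(states, cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 1])))
    rec.subject = subject
    return rec


# ---------------------------------------------------------------------------
# dependence kernel
# ---------------------------------------------------------------------------


def mi_kernel(x_i: np.ndarray, x_j: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) of two equal-length channel windows.

    Estimated from the joint 2-D histogram with ``n_bins`` equal-width bins
    per axis.  Symmetric and non-negative by construction.
    """
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise ValueError(f"length mismatch: {x_i.shape} vs {x_j.shape}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    joint, _, _ = np.histogram2d(x_i, x_j, bins=n_bins)
    p = joint / joint.sum()
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (pi @ pj)[mask])))


# ---------------------------------------------------------------------------
# corruption, preprocessing, augmentation
# ---------------------------------------------------------------------------


def corrupt(
    rec: SensorRecording,
    noise_sd: float = 0.0,
    mask_fraction: float = 0.0,
    seed: int = 0,
) -> SensorRecording:
    """Simulate sensor degradation: additive noise plus random channel masking.

    Adds ``N(0, noise_sd^2)`` to every sample of the retained (non-masked)
    channels and masks ``floor(mask_fraction * K)`` channels chosen uniformly
    without replacement.  The masking order is a seed-determined channel
    permutation, so for a fixed seed a higher fraction masks a superset of a
    lower fraction's channels (nested corruption levels).  Masked channels
    are set to the mask sentinel (0, which is also their value after
    z-scoring) and flagged in ``channel_meta``.  Already-masked channels stay
    masked (idempotent).
    """
    if not (0.0 <= mask_fraction <= 1.0):
        raise ValueError("mask_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    K = rec.n_channels
    n_mask = int(np.floor(mask_fraction * K))
    already = rec.masked_channels
    order = rng.permutation(K)
    newly = [k for k in order if not already[k]][: max(n_mask - already.sum(), 0)]
    masked = already.copy()
    masked[newly] = True

    X = rec.signals.copy()
    if noise_sd > 0:
        X[~masked] += noise_sd * rng.standard_normal(X[~masked].shape)
    X[masked] = 0.0
    meta = [dict(m, masked=bool(masked[k])) for k, m in enumerate(rec.channel_meta)]
    return SensorRecording(
        signals=X,
        sample_rate=rec.sample_rate,
        channel_meta=meta,
        labels=None if rec.labels is None else rec.labels.copy(),
        context=None if rec.context is None else rec.context.copy(),
        truth_states=None if rec.truth_states is None else rec.truth_states.copy(),
        truth_coupling=None if rec.truth_coupling is None else rec.truth_coupling.copy(),
        subject=rec.subject,
    )


def _zscore_guarded(w: np.ndarray) -> np.ndarray:
    """Per-channel z-score of one (K, L) window; constant channels map to zeros."""
    mean = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    sd = np.where(sd < _SD_GUARD, 1.0, sd)
    out = (w - mean) / sd
    # constant channels: force exact zeros (mean subtraction already ~0)
    return out


def preprocess_and_window(
    rec: SensorRecording,
    target_rate: float = 100.0,
    window_seconds: float = 5.0,
    overlap: float = 0.5,
) -> WindowBatch:
    """Resample, segment into overlapping windows, and z-score each window.

    Linear-interpolation resampling to ``target_rate``; sliding windows of
    ``window_seconds`` advancing by ``stride = L * (1 - overlap)`` samples;
    trailing partial windows are dropped.  Window labels are the majority
    per-sample label, ties broken toward the lower class index.
    """
    if rec.sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")

    K, T = rec.signals.shape
    if abs(rec.sample_rate - target_rate) < 1e-12:
        X = rec.signals
        labels = rec.labels
        context = rec.context
    else:
        t_old = np.arange(T) / rec.sample_rate
        T_new = int(np.floor((T - 1) * target_rate / rec.sample_rate)) + 1
        t_new = np.arange(T_new) / target_rate
        X = np.vstack([np.interp(t_new, t_old, rec.signals[k]) for k in range(K)])
        labels = None
        if rec.labels is not None:
            nearest = np.clip(np.round(t_new * rec.sample_rate).astype(int), 0, T - 1)
            labels = rec.labels[nearest]
        context = None
        if rec.context is not None:
            nearest = np.clip(np.round(t_new * rec.sample_rate).astype(int), 0, T - 1)
            context = rec.context[nearest]

    L = int(round(window_seconds * target_rate))
    stride = max(int(round(L * (1.0 - overlap))), 1)
    T_rs = X.shape[1]
    if T_rs < L:
        logger.warning(
            "recording of %d samples shorter than one window (%d); empty batch", T_rs, L
        )
        return WindowBatch(
            windows=np.empty((0, K, L)),
            window_labels=None if labels is None else np.empty(0, dtype=int),
            context=None,
            intervals=np.empty((0, 2), dtype=int),
            source_id=rec.subject,
            sample_rate=target_rate,
            masked_channels=rec.masked_channels,
        )

    starts = np.arange(0, T_rs - L + 1, stride)
    windows = np.stack([_zscore_guarded(X[:, s : s + L]) for s in starts])
    intervals = np.stack([starts, starts + L], axis=1)

    window_labels = None
    if labels is not None:
        window_labels = np.empty(len(starts), dtype=int)
        for n, s in enumerate(starts):
            counts = np.bincount(labels[s : s + L])
            window_labels[n] = int(np.argmax(counts))  # argmax takes lowest index on ties

    wctx = None
    if context is not None:
        wctx = np.stack([context[s : s + L].mean(axis=0) for s in starts])

    return WindowBatch(
        windows=windows,
        window_labels=window_labels,
        context=wctx,
        intervals=intervals,
        source_id=rec.subject,
        sample_rate=target_rate,
        masked_channels=rec.masked_channels,
        subjects=np.array([rec.subject] * len(starts)),
    )


@dataclass
class AugmentConfig:
    """Window augmentation settings; all perturbations off by default."""

    noise_prob: float = 0.0
    noise_sd: float = 0.05
    crop_prob: float = 0.0
    crop_fraction: float = 0.9  # keep this fraction, then re-stretch to L
    warp_prob: float = 0.0
    warp_strength: float = 0.1  # max relative timing displacement
    warp_cycles: int = 2

    def validate(self) -> None:
        for p in (self.noise_prob, self.crop_prob, self.warp_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("augmentation probabilities must be in [0, 1]")
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must be in (0, 1]")


def augment(batch: WindowBatch, cfg: AugmentConfig, seed: int = 0) -> WindowBatch:
    """Independently perturb each window; labels and shapes are unchanged.

    Perturbations: additive Gaussian noise; random crop to ``crop_fraction``
    followed by linear re-stretch to the window length; smooth monotone time
    warping by a low-frequency sinusoidal remapping.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    N, K, L = batch.windows.shape
    out = batch.windows.copy()
    grid = np.arange(L, dtype=float)
    for n in range(N):
        w = out[n]
        if cfg.crop_prob > 0 and rng.random() < cfg.crop_prob and cfg.crop_fraction < 1.0:
            Lc = max(int(round(cfg.crop_fraction * L)), 2)
            start = int(rng.integers(0, L - Lc + 1))
            src = np.linspace(start, start + Lc - 1, L)
            w = np.vstack([np.interp(src, grid, w[k]) for k in range(K)])
        if cfg.warp_prob > 0 and rng.random() < cfg.warp_prob and cfg.warp_strength > 0:
            phase = rng.uniform(0, 2 * np.pi)
            disp = cfg.warp_strength * L / (2 * np.pi * cfg.warp_cycles) * np.sin(
                2 * np.pi * cfg.warp_cycles * grid / L + phase
            )
            src = np.clip(grid + disp - disp[0], 0, L - 1)
            src = np.maximum.accumulate(src)  # enforce monotonicity
            w = np.vstack([np.interp(src, grid, w[k]) for k in range(K)])
        if cfg.noise_prob > 0 and rng.random() < cfg.noise_prob and cfg.noise_sd > 0:
            w = w + cfg.noise_sd * rng.standard_normal((K, L))
        out[n] = w
    return replace(batch, windows=out)


# ---------------------------------------------------------------------------
# canonical experiment configuration
# ---------------------------------------------------------------------------


def default_sim_config(
    seed: int = 0,
    duration: float = 240.0,
    n_sensors: int = 8,
    n_states: int = 3,
    noise_sd: float = 0.1,
    coupling_weight: float = 0.9,
) -> SimConfig:
    """The canonical study conditions used by the recovery experiments.

    Three latent states are frequency-coded into disjoint oscillation bands
    (roughly 1-4.5, 5.5-9 and 10-13.5 Hz at a 32 Hz rate); each sensor within
    a state oscillates at a distinct frequency 0.5 Hz apart so that uncoupled
    channels are near-orthogonal over a 2-s window.  Two sensor pairs,
    (0, 1) and (2, 3), share latent Ornstein-Uhlenbeck drivers — the ground
    truth coupling graph.  States dwell ~8 s on average.
    """
    if n_states <= 3:
        band_start = np.array([1.0, 5.5, 10.0])[:n_states]
    else:
        band_start = np.linspace(1.0, 10.0, n_states)
    templates = np.zeros((n_states, n_sensors, 3))
    for s in range(n_states):
        for k in range(n_sensors):
            templates[s, k] = (0.0, band_start[s] + (0.5 * k) % 4.0, 1.0)
    off = 0.5 / (n_states - 1)
    trans = np.full((n_states, n_states), off)
    np.fill_diagonal(trans, 0.5)
    sample_rate = 32.0
    return SimConfig(
        n_sensors=n_sensors,
        n_states=n_states,
        transition_matrix=trans,
        emission_templates=templates,
        noise_sd=noise_sd,
        coupling_edges=((0, 1, coupling_weight), (2, 3, coupling_weight)),
        sample_rate=sample_rate,
        duration=duration,
        dwell_scale=8.0 * sample_rate,
        seed=seed,
    )
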