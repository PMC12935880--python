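"""Training, evaluation, cross-validation and the simulation experiments.

The harness trains the PGIN (+ optionally joint AHSIM) stack with Adam,
step-decayed learning rate and early stopping, computes the standard
classification metric surface (accuracy / precision / recall / macro-F1 /
one-vs-rest macro AUC) plus selective-prediction statistics, and implements
the robustness (noise + channel masking) and latent-state/graph recovery
experiments on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import synthgen
from .ahsim import AhsimParams, ahsim_forward, ahsim_loss, coarsen, init_ahsim_params
from .autodiff import Adam, Var
from .pgin_core import PginParams, init_pgin_params, pgin_forward
from .pgin_heads import HeadParams, decode, init_head_params, pgin_loss, uncertainty
from .synthgen import SensorRecording, SimConfig, WindowBatch, corrupt, preprocess_and_window

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "PhysioGraphModel",
    "train",
    "evaluate",
    "cross_validate",
    "robustness_experiment",
    "recovery_experiment",
    "template_oracle_predict",
    "coupling_auc",
    "merge_batches",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the experimental protocol:
    Adam, lr 1e-3 decayed ×0.1 every 10 epochs, batch 64, up to 100 epochs
    with patience 20, dropout 0.3, weight decay 1e-5)."""

    lr: float = 1e-3
    lr_decay: float = 0.1
    lr_decay_every: int = 10
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 20
    dropout: float = 0.3
    weight_decay: float = 1e-5
    channel_dropout: float = 0.1  # masked-dropout: P(drop each channel) per batch
    seed: int = 0
    seeds: tuple = (0, 1, 2, 3, 4)
    beta: float = 0.005
    beta_warmup_epochs: int = 5  # linear KL annealing from 0 to beta
    rho: float = 0.05
    lambda_trust: float = 0.1
    lambda_hier: float = 0.5
    prior_mode: str = "standard"
    joint_ahsim: bool = True
    early_stop_on: str = "loss"  # or "accuracy"

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class EvalReport:
    """Metric surface of one evaluation (all metrics in [0, 1])."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    n: int
    deferral_rate: float = 0.0
    selective_accuracy: float | None = None
    per_class_support: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "n": self.n,
            "deferral_rate": self.deferral_rate,
            "selective_accuracy": self.selective_accuracy,
        }


class PhysioGraphModel:
    """PGIN + AHSIM parameter bundle with batched forward/loss/predict."""

    def __init__(
        self,
        pgin: PginParams,
        heads: HeadParams,
        ahsim: AhsimParams | None = None,
        n_classes: int = 2,
    ):
        self.pgin = pgin
        self.heads = heads
        self.ahsim = ahsim
        self.n_classes = n_classes

    @classmethod
    def build(
        cls,
        n_sensors: int,
        n_classes: int,
        d_c: int = 0,
        d_h: int = 8,
        d_g: int = 8,
        d_z: int = 8,
        d_r: int = 16,
        seed: int = 0,
        hierarchy: dict | None = None,
        edge_kernel: str = "similarity",
        tau_u: float = 1.0,
        beta: float = 0.005,
        rho: float = 0.05,
        class_weights: np.ndarray | None = None,
        theta0: float = 0.5,
    ) -> "PhysioGraphModel":
        pgin = init_pgin_params(
            n_sensors, d_h=d_h, d_g=d_g, d_z=d_z, d_r=d_r, seed=seed, edge_kernel=edge_kernel
        )
        heads = init_head_params(
            d_z, n_classes, d_c=d_c, seed=seed, tau_u=tau_u, beta=beta, rho=rho,
            class_weights=class_weights,
        )
        ah = init_ahsim_params(d_z, n_classes, d_c=d_c, seed=seed, hierarchy=hierarchy, theta0=theta0)
        return cls(pgin, heads, ah, n_classes=n_classes)

    # -- parameters --------------------------------------------------------
    def parameters(self, joint: bool = True) -> list[Var]:
        out = self.pgin.parameters() + self.heads.parameters()
        if joint and self.ahsim is not None:
            out += self.ahsim.parameters()
        return out

    def state_values(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters(joint=True)]

    def load_state_values(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(joint=True), values):
            p.value[...] = v

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        windows: np.ndarray,
        context: np.ndarray | None = None,
        masked: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        sample: bool = True,
        dropout: float = 0.0,
        with_ahsim: bool = True,
    ) -> dict:
        if rng is None:
            rng = np.random.default_rng(0)
        need_prior = self.heads is not None and getattr(self, "_prior_mode", "standard") == "learned"
        out = pgin_forward(
            windows, self.pgin, masked=masked, rng=rng, sample=sample, need_prior=need_prior
        )
        z = out["z_hat"]
        if dropout > 0:
            keep = (rng.random(z.shape) >= dropout) / (1.0 - dropout)
            z = z * keep
        N, L, _ = z.shape
        ctx = None
        if context is not None and context.size:
            ctx = np.broadcast_to(context[:, None, :], (N, L, context.shape[-1]))
        from .pgin_heads import calibrate

        z_cal = calibrate(z, ctx, self.heads)
        probs = decode(z_cal, ctx, self.heads)  # (N, L, |Y|)
        U = uncertainty(probs, self.heads.tau_u)  # (N, L)
        out.update({"probs": probs, "U": U, "z_cal": z_cal})
        if with_ahsim and self.ahsim is not None:
            out["ahsim"] = ahsim_forward(out["z_hat"], probs, U, None, self.ahsim)
        return out

    def loss(
        self,
        fwd: dict,
        labels: np.ndarray,
        config: TrainConfig,
    ) -> tuple[Var, dict]:
        total, comps = pgin_loss(
            fwd["probs"],
            labels,
            fwd["mu"],
            fwd["logvar"],
            fwd["A"],
            self.heads,
            prior_mode=config.prior_mode,
            prior_mean=fwd.get("prior_mean"),
        )
        if config.joint_ahsim and "ahsim" in fwd and self.ahsim is not None:
            ah = fwd["ahsim"]
            y_coarse = None
            coarse_labels = None
            if self.ahsim.hierarchy:
                y_coarse = coarsen(ah["pi"], self.ahsim.hierarchy)
                coarse_labels = np.array([self.ahsim.hierarchy[int(y)] for y in labels])
            ah_total, ah_comps = ahsim_loss(
                ah["pi"], labels, ah["l_trust"], y_coarse, coarse_labels,
                config.lambda_trust, config.lambda_hier,
            )
            total = total + ah_total
            comps.update({f"ahsim_{k}": v for k, v in ah_comps.items()})
        return total, comps

    # -- prediction ---------------------------------------------------------
    def predict(
        self,
        batch: WindowBatch,
        rng: np.random.Generator | None = None,
        sample: bool = False,
        batch_size: int = 128,
    ) -> dict:
        """Deterministic-by-default predictions for a window batch.

        Returns window-level distributions ``pi`` (AHSIM-gated when
        available, else time-averaged decoder output), per-window mean
        uncertainty, thresholds and emit/defer decisions.
        """
        if rng is None:
            rng = np.random.default_rng(0)
        pis, mean_u, thetas = [], [], []
        masked = batch.masked_channels
        for a in range(0, batch.n_windows, batch_size):
            w = batch.windows[a : a + batch_size]
            ctx = None if batch.context is None else batch.context[a : a + batch_size]
            fwd = self.forward(w, ctx, masked=masked, rng=rng, sample=sample, with_ahsim=True)
            if "ahsim" in fwd:
                pi = fwd["ahsim"]["pi"].value
            else:
                pi = fwd["probs"].value.mean(axis=1)
            U = fwd["U"].value  # (n, L)
            z = fwd["z_hat"].value
            var_z = z.var(axis=-1)  # (n, L)
            th = np.clip(
                self.ahsim.theta0
                + self.ahsim.eps_theta * U
                + self.ahsim.zeta * var_z,
                0.0,
                1.0,
            ).mean(axis=1) if self.ahsim is not None else np.zeros(len(w))
            pis.append(pi)
            mean_u.append(U.mean(axis=1))
            thetas.append(th)
        pi = np.concatenate(pis)
        theta = np.concatenate(thetas)
        y_pred = pi.argmax(axis=1)
        emitted = pi.max(axis=1) >= theta
        return {
            "pi": pi,
            "y_pred": y_pred,
            "mean_U": np.concatenate(mean_u),
            "theta": theta,
            "emitted": emitted,
        }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _check_finite(total: Var, comps: dict) -> None:
    if np.isfinite(float(total.value)):
        return
    for name, v in comps.items():
        val = float(v.value) if isinstance(v, Var) else float(v)
        if not np.isfinite(val):
            raise RuntimeError(f"divergent loss: component '{name}' is non-finite")
    raise RuntimeError("divergent loss: total is non-finite")


def train(
    model: PhysioGraphModel,
    train_batch: WindowBatch,
    val_batch: WindowBatch,
    config: TrainConfig,
) -> tuple[PhysioGraphModel, list[dict]]:
    """Fit the model, returning the best-validation checkpoint and a history.

    Minimizes the composite objective with Adam (decoupled weight decay),
    decaying the learning rate by ``lr_decay`` every ``lr_decay_every``
    epochs, and early-stops when validation loss has not improved for
    ``patience`` epochs.  Fully reproducible from ``config.seed``.
    """
    if train_batch.n_windows == 0 or val_batch.n_windows == 0:
        raise ValueError("need at least one training and one validation window")
    labels = train_batch.window_labels
    if labels is None:
        raise ValueError("training requires window labels")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    params = model.parameters(joint=config.joint_ahsim)
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    model._prior_mode = config.prior_mode

    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_values()
    since_best = 0
    N = train_batch.n_windows
    K = train_batch.n_channels
    base_beta = model.heads.beta
    for epoch in range(config.max_epochs):
        opt.lr = config.lr * config.lr_decay ** (epoch // config.lr_decay_every)
        if config.beta_warmup_epochs > 0:  # KL annealing
            model.heads.beta = base_beta * min(1.0, (epoch + 1) / config.beta_warmup_epochs)
        order = rng.permutation(N)
        ep_comps: dict[str, float] = {}
        n_batches = 0
        for a in range(0, N, config.batch_size):
            idx = order[a : a + config.batch_size]
            w = train_batch.windows[idx]
            ctx = None if train_batch.context is None else train_batch.context[idx]
            masked = None
            if config.channel_dropout > 0:
                cand = rng.random(K) < config.channel_dropout
                if cand.sum() < K:  # never mask every channel
                    masked = cand
            fwd = model.forward(
                w, ctx, masked=masked, rng=rng, sample=True,
                dropout=config.dropout, with_ahsim=config.joint_ahsim,
            )
            total, comps = model.loss(fwd, labels[idx], config)
            _check_finite(total, comps)
            opt.zero_grad()
            total.backward()
            opt.step()
            n_batches += 1
            ep_comps["total"] = ep_comps.get("total", 0.0) + float(total.value)
            for k, v in comps.items():
                val = float(v.value) if isinstance(v, Var) else float(v)
                ep_comps[k] = ep_comps.get(k, 0.0) + val
        ep_comps = {k: v / n_batches for k, v in ep_comps.items()}

        # validation always scores with the full KL weight so epochs compare
        model.heads.beta = base_beta
        val_loss, val_acc = _validation_loss(model, val_batch, config)
        entry = {"epoch": epoch, "lr": opt.lr, "val_loss": val_loss, "val_accuracy": val_acc}
        entry.update({f"train_{k}": v for k, v in ep_comps.items()})
        history.append(entry)
        score = val_loss if config.early_stop_on == "loss" else -val_acc
        if score < best_val - 1e-9:
            best_val = score
            best_state = model.state_values()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
    model.heads.beta = base_beta
    model.load_state_values(best_state)
    return model, history


def _validation_loss(
    model: PhysioGraphModel, batch: WindowBatch, config: TrainConfig
) -> tuple[float, float]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    total_loss = 0.0
    n = 0
    correct = 0
    for a in range(0, batch.n_windows, config.batch_size):
        w = batch.windows[a : a + config.batch_size]
        ctx = None if batch.context is None else batch.context[a : a + config.batch_size]
        fwd = model.forward(
            w, ctx, masked=batch.masked_channels, rng=rng, sample=False,
            with_ahsim=config.joint_ahsim,
        )
        labels = batch.window_labels[a : a + config.batch_size]
        total, _ = model.loss(fwd, labels, config)
        total_loss += float(total.value) * len(w)
        if "ahsim" in fwd:
            pred = fwd["ahsim"]["pi"].value.argmax(axis=1)
        else:
            pred = fwd["probs"].value.mean(axis=1).argmax(axis=1)
        correct += int((pred == labels).sum())
        n += len(w)
    return total_loss / n, correct / n


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _metric_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probs: np.ndarray | None,
    emitted: np.ndarray | None = None,
) -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float((y_true == y_pred).mean())
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    auc = None
    if probs is not None and len(np.unique(y_true)) > 1:
        try:
            present = np.unique(y_true)
            if probs.shape[1] == 2:
                auc = float(roc_auc_score(y_true, probs[:, 1]))
            elif len(present) == probs.shape[1]:
                auc = float(roc_auc_score(y_true, probs, multi_class="ovr", average="macro"))
            else:  # restrict to classes present, renormalize
                sub = probs[:, present]
                sub = sub / sub.sum(axis=1, keepdims=True)
                remap = {c: i for i, c in enumerate(present)}
                auc = float(
                    roc_auc_score(
                        np.array([remap[c] for c in y_true]), sub,
                        multi_class="ovr", average="macro",
                    )
                )
        except ValueError:
            auc = None
    defer_rate = 0.0
    sel_acc = None
    if emitted is not None:
        defer_rate = float(1.0 - emitted.mean())
        if emitted.any():
            sel_acc = float((y_true[emitted] == y_pred[emitted]).mean())
    return EvalReport(
        accuracy=acc,
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        auc=auc,
        n=len(y_true),
        deferral_rate=defer_rate,
        selective_accuracy=sel_acc,
        per_class_support=support,
    )


def evaluate(
    model: PhysioGraphModel,
    batch: WindowBatch,
    defer_policy: str = "report",
    rng: np.random.Generator | None = None,
    sample: bool = False,
) -> EvalReport:
    """Evaluate on a labelled window batch.

    ``defer_policy``: "report" computes overall metrics on all windows and
    selective accuracy on the emitted subset; "as_error" counts deferred
    windows as errors in ``accuracy``.
    """
    if batch.window_labels is None:
        raise ValueError("evaluation requires labels")
    pred = model.predict(batch, rng=rng, sample=sample)
    y_true = batch.window_labels
    report = _metric_report(y_true, pred["y_pred"], pred["pi"], pred["emitted"])
    if defer_policy == "as_error":
        acc = float(((y_true == pred["y_pred"]) & pred["emitted"]).mean())
        report.accuracy = acc
    return report


def summarize_reports(reports: list[EvalReport]) -> dict:
    """Mean ± sd over per-seed reports (sd reported when >= 2 seeds)."""
    out = {}
    for key in ("accuracy", "precision", "recall", "f1", "auc", "deferral_rate",
                "selective_accuracy"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if not vals:
            out[key] = {"mean": None, "sd": None}
            continue
        out[key] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
        }
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def merge_batches(batches: list[WindowBatch]) -> WindowBatch:
    """Concatenate window batches from multiple recordings (shared geometry)."""
    return WindowBatch(
        windows=np.concatenate([b.windows for b in batches]),
        window_labels=(
            None
            if batches[0].window_labels is None
            else np.concatenate([b.window_labels for b in batches])
        ),
        context=(
            None if batches[0].context is None else np.concatenate([b.context for b in batches])
        ),
        intervals=np.concatenate([b.intervals for b in batches]),
        source_id=",".join(b.source_id for b in batches),
        sample_rate=batches[0].sample_rate,
        masked_channels=batches[0].masked_channels,
        subjects=np.concatenate(
            [
                b.subjects if b.subjects is not None else np.array([b.source_id] * b.n_windows)
                for b in batches
            ]
        ),
    )


def _subset(batch: WindowBatch, idx: np.ndarray) -> WindowBatch:
    return replace(
        batch,
        windows=batch.windows[idx],
        window_labels=None if batch.window_labels is None else batch.window_labels[idx],
        context=None if batch.context is None else batch.context[idx],
        intervals=batch.intervals[idx],
        subjects=None if batch.subjects is None else batch.subjects[idx],
    )


def cross_validate(
    dataset: WindowBatch,
    scheme: str = "loso",
    n_folds: int = 5,
    train_fn=None,
    seed: int = 0,
) -> list[dict]:
    """Leave-one-subject-out or stratified k-fold cross-validation.

    ``train_fn(train_batch, test_batch) -> EvalReport`` does the actual
    fitting/scoring; when omitted, a small default PGIN training is used.
    LOSO folds are verified leakage-free (a subject in both sides of a fold
    is a hard failure).
    """
    if train_fn is None:
        def train_fn(tr: WindowBatch, te: WindowBatch) -> EvalReport:  # pragma: no cover
            n_classes = int(np.max(dataset.window_labels)) + 1
            model = PhysioGraphModel.build(tr.n_channels, n_classes, seed=seed)
            cfg = TrainConfig(max_epochs=10, patience=5, seed=seed, batch_size=32)
            model, _ = train(model, tr, te, cfg)
            return evaluate(model, te)

    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "loso":
        if dataset.subjects is None:
            raise ValueError("LOSO requires subject identifiers")
        for subject in np.unique(dataset.subjects):
            test = np.where(dataset.subjects == subject)[0]
            trainset = np.where(dataset.subjects != subject)[0]
            folds.append((trainset, test))
    elif scheme == "kfold":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(dataset.windows[:, 0, 0], dataset.window_labels):
            folds.append((tr, te))
    else:
        raise ValueError(f"unknown scheme '{scheme}'")

    results = []
    for i, (tr_idx, te_idx) in enumerate(folds):
        if scheme == "loso":
            overlap = set(dataset.subjects[tr_idx]) & set(dataset.subjects[te_idx])
            if overlap:
                raise RuntimeError(f"subject leakage in fold {i}: {sorted(overlap)}")
        report = train_fn(_subset(dataset, tr_idx), _subset(dataset, te_idx))
        results.append(
            {
                "fold": i,
                "test_subject": (
                    str(dataset.subjects[te_idx[0]]) if scheme == "loso" else None
                ),
                "n_train": len(tr_idx),
                "n_test": len(te_idx),
                "report": report,
            }
        )
    return results


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def robustness_experiment(
    model: PhysioGraphModel,
    recording: SensorRecording,
    levels: tuple = (0.0, 0.1, 0.2, 0.3),
    noise_sd: float = 0.1,
    seeds: tuple = (0, 1, 2, 3, 4),
    target_rate: float | None = None,
    window_seconds: float = 2.0,
) -> dict:
    """Evaluate under increasing sensor corruption (noise + channel masking).

    Level 0 is the clean evaluation; level ℓ > 0 adds N(0, noise_sd²) to the
    retained channels and masks ⌊ℓ·K⌋ channels.  Reports per-(level, seed)
    rows, per-level mean ± sd, mean per-step uncertainty, and the verdict of
    whether accuracy is non-increasing in the corruption level.
    """
    if target_rate is None:
        target_rate = recording.sample_rate
    rows = []
    per_level: dict[float, list[EvalReport]] = {lv: [] for lv in levels}
    u_clean, u_corrupt = [], []
    for lv in levels:
        for sd_seed in seeds:
            if lv == 0.0:
                rec = recording
            else:
                rec = corrupt(recording, noise_sd=noise_sd, mask_fraction=lv, seed=int(sd_seed))
            batch = preprocess_and_window(rec, target_rate, window_seconds)
            pred = model.predict(batch, rng=np.random.default_rng(int(sd_seed)))
            rep = _metric_report(batch.window_labels, pred["y_pred"], pred["pi"], pred["emitted"])
            rows.append({"level": lv, "seed": int(sd_seed), **rep.as_dict(),
                         "mean_U": float(pred["mean_U"].mean())})
            per_level[lv].append(rep)
            (u_clean if lv == 0.0 else u_corrupt).append(float(pred["mean_U"].mean()))
            if lv == 0.0:
                break  # clean evaluation is deterministic; one row suffices
    summary = {
        lv: {
            "accuracy_mean": float(np.mean([r.accuracy for r in reps])),
            "accuracy_sd": (
                float(np.std([r.accuracy for r in reps], ddof=1)) if len(reps) > 1 else None
            ),
            "f1_mean": float(np.mean([r.f1 for r in reps])),
        }
        for lv, reps in per_level.items()
    }
    accs = [summary[lv]["accuracy_mean"] for lv in levels]
    monotone = all(a + 1e-9 >= b for a, b in zip(accs, accs[1:]))
    return {
        "rows": rows,
        "summary": summary,
        "monotone_accuracy": bool(monotone),
        "mean_U_clean": float(np.mean(u_clean)),
        "mean_U_corrupt": float(np.mean(u_corrupt)) if u_corrupt else None,
    }


def template_oracle_predict(batch: WindowBatch, cfg: SimConfig) -> np.ndarray:
    """Nearest-template (matched-filter) state classifier.

    Projects each channel onto the sin/cos pair at each state's template
    frequency for that channel and scores states by total captured energy —
    the separability oracle for frequency-coded templates.
    """
    N, K, L = batch.windows.shape
    t = np.arange(L) / batch.sample_rate
    preds = np.empty(N, dtype=int)
    # (n_states, K, L) matched filters
    freqs = cfg.emission_templates[:, :, 1]
    sin = np.sin(2 * np.pi * freqs[:, :, None] * t)
    cos = np.cos(2 * np.pi * freqs[:, :, None] * t)
    for n in range(N):
        w = batch.windows[n]  # (K, L)
        energy = (np.einsum("kl,skl->sk", w, sin) ** 2 + np.einsum("kl,skl->sk", w, cos) ** 2)
        preds[n] = int(energy.sum(axis=1).argmax())
    return preds


def coupling_auc(A_mean_offdiag: np.ndarray, truth_coupling: np.ndarray) -> float:
    """Ranking AUC of learned off-diagonal adjacency against the true coupling
    edge set (upper-triangle pairs; Mann-Whitney formulation)."""
    K = truth_coupling.shape[0]
    iu = np.triu_indices(K, k=1)
    scores = A_mean_offdiag[iu]
    labels = (truth_coupling[iu] > 0).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("coupling truth has no positive/negative pairs")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(greater / (len(pos) * len(neg)))


def _simulate_split(
    cfg: SimConfig, durations: tuple[float, float, float], window_seconds: float
) -> tuple[WindowBatch, WindowBatch, WindowBatch, SensorRecording]:
    """Independent train/val/test recordings (no window leakage across splits)."""
    batches = []
    test_rec = None
    for i, dur in enumerate(durations):
        c = replace(cfg, duration=dur, seed=cfg.seed + 1000 * i)
        rec = synthgen.simulate_recording(c, subject=f"S{i}")
        if i == 2:
            test_rec = rec
        batches.append(preprocess_and_window(rec, cfg.sample_rate, window_seconds))
    return batches[0], batches[1], batches[2], test_rec


def recovery_experiment(
    sim_cfg: SimConfig | None = None,
    train_cfg: TrainConfig | None = None,
    window_seconds: float = 2.0,
    durations: tuple = (1440.0, 160.0, 200.0),
    shuffle_labels: bool = False,
    corruption: tuple = (0.1, 0.25),
) -> dict:
    """Simulate, train, and measure latent-state and graph recovery.

    Reports held-out accuracy vs chance, the matched-filter oracle accuracy
    (separability certificate), coupling-recovery AUC of the time-averaged
    learned adjacency (with the mutual-information baseline as feasibility
    reference), and mean uncertainty on clean vs corrupted inputs.
    ``shuffle_labels`` permutes training labels for the no-leakage null.
    """
    if sim_cfg is None:
        sim_cfg = synthgen.default_sim_config()
    if train_cfg is None:
        train_cfg = TrainConfig(max_epochs=30, patience=29, seed=sim_cfg.seed)
    tr, va, te, te_rec = _simulate_split(sim_cfg, durations, window_seconds)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 303]))
    if shuffle_labels:
        tr = replace(tr, window_labels=rng.permutation(tr.window_labels))
        va = replace(va, window_labels=rng.permutation(va.window_labels))

    n_classes = sim_cfg.n_states
    hierarchy = {j: min(j, 1) for j in range(n_classes)}  # first two fine states share a coarse class
    model = PhysioGraphModel.build(
        sim_cfg.n_sensors, n_classes, seed=train_cfg.seed, hierarchy=hierarchy
    )
    model, history = train(model, tr, va, train_cfg)

    report = evaluate(model, te)
    oracle_pred = template_oracle_predict(te, sim_cfg)
    oracle_acc = float((oracle_pred == te.window_labels).mean())

    # graph recovery: time-averaged learned adjacency on held-out windows
    A_sum = np.zeros((sim_cfg.n_sensors, sim_cfg.n_sensors))
    n_seen = 0
    for a in range(0, te.n_windows, 128):
        fwd = pgin_forward(te.windows[a : a + 128], model.pgin, sample=False)
        A_sum += fwd["A"].value.sum(axis=(0, 1))
        n_seen += fwd["A"].value.shape[0] * fwd["A"].value.shape[1]
    A_mean = A_sum / n_seen
    np.fill_diagonal(A_mean, 0.0)
    auc_learned = coupling_auc(A_mean, te_rec.truth_coupling)

    mi = np.zeros_like(A_mean)
    for i in range(sim_cfg.n_sensors):
        for j in range(i + 1, sim_cfg.n_sensors):
            vals = [
                synthgen.mi_kernel(w[i], w[j], n_bins=8) for w in te.windows[:: max(te.n_windows // 50, 1)]
            ]
            mi[i, j] = mi[j, i] = float(np.mean(vals))
    auc_mi = coupling_auc(mi, te_rec.truth_coupling)

    # uncertainty response to corruption
    noise_sd, mask_fraction = corruption
    te_corrupt = corrupt(te_rec, noise_sd=noise_sd, mask_fraction=mask_fraction,
                         seed=train_cfg.seed)
    te_c = preprocess_and_window(te_corrupt, sim_cfg.sample_rate, window_seconds)
    pred_clean = model.predict(te)
    pred_corrupt = model.predict(te_c)

    return {
        "model": model,
        "history": history,
        "test_report": report,
        "test_accuracy": report.accuracy,
        "chance": 1.0 / n_classes,
        "oracle_accuracy": oracle_acc,
        "coupling_auc": auc_learned,
        "coupling_auc_mi_baseline": auc_mi,
        "adjacency_mean": A_mean,
        "mean_U_clean": float(pred_clean["mean_U"].mean()),
        "mean_U_corrupt": float(pred_corrupt["mean_U"].mean()),
        "test_batch": te,
        "test_recording": te_rec,
        "n_train_windows": tr.n_windows,
        "n_test_windows": te.n_windows,
    }
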