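# physiograph

Uncertainty-aware health-state inference from multichannel biosignal
streams, for researchers and engineers building interpretable diagnostic
pipelines on wearable or bedside sensor data.

Raw multivariate physiology (ECG, PPG, EMG, EDA, ...) is modeled as noisy
emissions of a latent Markov health state z(t).  The package provides:

- **PGIN** — a dynamic-graph variational encoder: per-sensor frame encoders
  h_k(t) = σ(W_k x_k(t) + b_k); a time-varying symmetric sensor adjacency
  A_t built from pairwise embedding similarity (row-softmax S, then
  A = (S + Sᵀ)/2, so A is symmetric with entries in (0,1) and total mass
  K); one graph-convolution step H̃_t = σ(A_t H_t W + b); and a
  bidirectional-RNN Gaussian posterior q(z_t) = N(μ_t, diag σ_t²) sampled
  by reparameterization.  Trained with
  L = mean CE + β·KL(q‖p) + ρ·Σ_t‖A_t − A_{t−1}‖_F².
- **AHSIM** — adaptive selective inference on top of the latent path:
  gated evidence recursion s(t) = (1−α_t)s(t−1) + α_t softmax(W_s ẑ_t),
  temporal attention pooling S_agg = Σ_t η(t)s(t), a risk-gated decision
  π_j ∝ exp(γS_agg[j] − λ_u U_agg[j] + ν m_j), entropy-gated trust
  regularization, coarse/fine hierarchical class probabilities, and an
  adaptive deferral threshold θ_t = θ₀ + ε_θU(t) + ζVar(ẑ_t) — emit the
  argmax only when max_j π_j ≥ θ, otherwise abstain.
- **A latent-Markov biosignal simulator** that realizes the same generative
  assumptions (state-conditioned waveform templates, shared drivers on
  coupled channel pairs, Gaussian noise) plus the standard preprocessing
  (100 Hz resampling, 5-s windows at 50 % overlap, per-window z-scoring),
  augmentation, and corruption (additive noise, channel masking) protocols.
- **A harness** for training (Adam, lr 1e-3 decayed ×0.1/10 epochs, early
  stopping), evaluation (accuracy/precision/recall/macro-F1/OvR-AUC plus
  deferral-aware selective metrics), LOSO and stratified k-fold
  cross-validation, and the robustness / recovery experiments.

Everything differentiable runs on the package's own reverse-mode autodiff
tape over NumPy (`physiograph.autodiff`) — no deep-learning framework
dependency.

## Worked example

```python
import numpy as np
import physiograph as pg
from physiograph.harness import recovery_experiment, TrainConfig

res = recovery_experiment(
    pg.default_sim_config(seed=1),          # 3 states, 8 sensors, 2 coupled pairs
    TrainConfig(max_epochs=30, patience=29, seed=1),
)
print(f"held-out accuracy : {res['test_accuracy']:.3f} (chance {res['chance']:.2f})")
print(f"template oracle   : {res['oracle_accuracy']:.3f}")
print(f"coupling AUC      : {res['coupling_auc']:.3f} "
      f"(MI baseline {res['coupling_auc_mi_baseline']:.3f})")
print(f"mean U clean/corr : {res['mean_U_clean']:.3f} / {res['mean_U_corrupt']:.3f}")
```

Output:

```
held-out accuracy : 0.985 (chance 0.33)
template oracle   : 0.995
coupling AUC      : 1.000 (MI baseline 1.000)
mean U clean/corr : 0.537 / 0.581
```

Reading: the trained model classifies held-out windows of the simulated
3-state signal at 98.5 % (a matched-filter oracle certifies the data are
separable at 99.5 %); the time-averaged learned adjacency ranks the two
truly coupled sensor pairs above all 26 uncoupled pairs (AUC 1.0); and the
entropy uncertainty rises when inputs are corrupted — the behavior the
deferral rule relies on.

The same pipeline is available from the shell:

```bash
physiograph simulate --config cfg.yaml --out rec.h5 --seed 17
physiograph train    --data rec.h5 --config cfg.yaml --out run/ --seed 17
physiograph eval     --run run/ --data rec.h5 --corrupt 0.2
physiograph infer    --run run/ --data rec.h5         # no labels needed
physiograph explain  --run run/ --data rec.h5 --window 3
```

`explain` exports the per-window diagnostic trace (attention weights,
uncertainty, latent trajectory, adjacency heatmap data, and the emit/defer
decision record).  File layouts are documented in `docs/FORMAT.md`; the
modeling choices in `docs/methods.md`.

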