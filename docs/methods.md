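# Methods

This note documents the models implemented in `physiograph`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Problem setting

A wearable or bedside platform records K biosensor channels (ECG, PPG, EMG,
EDA, ...) as a multivariate time series X ∈ R^{K×T}.  The working assumption
is a generative hierarchy: an unobserved, slowly varying health state z(t)
evolves as a Markov chain, P(z_t | z_{t−1}) = T_θ(z_{t−1}); each channel is
a noisy, conditionally independent emission x_k(t) ~ P(x_k | z(t), ε_k); and
inter-sensor dependence is time-varying, summarized by a dynamic graph whose
edge weights reflect mutual information or embedding similarity between
channels.  The task is to classify windows of X into diagnostic classes
while (a) exposing the latent trajectory and the sensor-dependency graph as
interpretable artifacts, (b) quantifying predictive uncertainty, and (c)
abstaining (deferring to a human) when confidence is insufficient.

## PGIN: dynamic-graph variational encoder

Per model timestep t, each channel contributes a **frame** of d_k
consecutive samples (default d_k = 8, hop 4).  Treating a short frame —
rather than a single scalar — as the sensor observation at t lets the
encoders see local waveform shape (slope, curvature, oscillation rate),
which is what distinguishes physiological regimes after per-window
normalization has removed level and scale.

1. **Sensor encoders.**  h_k(t) = σ(W_k x_k(t) + b_k), one affine map per
   sensor, σ = ReLU, giving node embeddings H_t ∈ R^{K×d_h}.
2. **Dynamic adjacency.**  Pairwise scores are mapped through a row-wise
   softmax S and symmetrized, A_t = (S + Sᵀ)/2: symmetric, entries in
   (0, 1), total mass K.  (Half the sum of the row-softmaxes of a score
   matrix and its transpose is *not* symmetric in general; symmetrizing the
   single row-softmax is, and preserves the stochastic mass.)  A global
   softmax variant (total mass 1) is available via
   `adjacency_mode="global"`.
3. **Edge kernel.**  The default scorer is a projected similarity kernel
   score(i, j) = (P h_i)·(P h_j)/√d_h with a shared learned projection P.
   A similarity kernel is the natural reading of a dependence graph built
   from "mutual information or embedding similarity": it is sign-consistent
   (PᵀP is positive semidefinite), so channels whose embeddings co-vary get
   larger weights, and the time-averaged adjacency is interpretable as a
   dependency estimate.  A one-hidden-layer MLP scorer on [h_i, h_j] is
   provided (`edge_kernel="mlp"`) but its response to inter-channel
   correlation has an arbitrary sign at initialization, which makes the
   recovered graph uninterpretable without additional constraints.
4. **Propagation and pooling.**  One graph-convolution layer
   H̃_t = σ(A_t H_t W + b), then mean-pooling over sensors (masked channels
   are excluded from the mean).
5. **Variational latent path.**  A bidirectional tanh RNN (directions
   summed) over the pooled sequence produces per-step Gaussian posterior
   parameters (μ_t, log σ_t²); the latent path is sampled by
   reparameterization, ẑ_t = μ_t + σ_t ε_t.  A forward-only mode
   (`bidirectional=False`) provides a causal/streaming variant.
6. **Decoder and uncertainty.**  ŷ(t) = softmax(W_y[ẑ_t, c_t] + b_y), with
   optional context covariates c and a context-modulated affine calibration
   h̃ = (1 + g_scale(c))⊙h + g_shift(c) that reduces to the identity without
   context.  Uncertainty is normalized temperature-scaled entropy
   U(t) = H(ŷ(t)) / (τ_u ln |Y|), so U ∈ [0, 1] at τ_u = 1.

**Objective.**  L = mean_t wCE(ŷ(t), y) + β·L_KL + ρ·Σ_t‖A_t − A_{t−1}‖_F².
The KL term regularizes the posterior toward N(0, I) by default; a learned
prior mode uses the latent transition tanh(W_z[ẑ_{t−1}, h̄_t] + b_z) as the
prior mean instead (`prior_mode="learned"`).  Window-level labels are
broadcast over timesteps.  β = 0.005 and ρ = 0.05 by default, chosen once so
that each weighted term is of order 1 at initialization on the reference
simulation (no single objective dominates); β is annealed linearly over the
first 5 epochs (standard practice for sequential variational models — it
prevents the KL from collapsing the latent code before the classifier finds
signal).

## AHSIM: adaptive selective inference

Operating on the PGIN outputs per window:

- **Evidence recursion.**  s(t) = (1 − α_t)s(t−1) + α_t softmax(W_s ẑ_t + b_s)
  with gate α_t = sigmoid(W_α[U(t), δ(t)] + b_α), δ(t) = ‖ẑ_t − ẑ_{t−1}‖₂
  (smoothed at the origin for differentiability).  Convexity keeps s(t) on
  the simplex.  The gate reacts faster under high uncertainty or rapid
  latent change and freezes under stability.
- **Temporal attention.**  η = softmax_t(vᵀ tanh(W_η[ẑ_t, c_t] + b_η)),
  S_agg = Σ_t η(t)s(t).
- **Risk-gated decision.**  π_j ∝ exp(γ S_agg[j] − λ_u U_agg[j] + ν m_j)
  with medical risk priors m.  U_agg[j] is the across-time standard
  deviation of ŷ_j(t) — a per-class dispersion measure; a class-constant
  (scalar) U_agg provably cancels in the softmax and is kept only behind
  `uagg_mode="scalar"`.
- **Trust gate.**  L_trust = mean_t sigmoid(w_Tᵀẑ_t + b_T)·KL(ŷ(t) ‖ π).
  The divergence is taken against the gated distribution π (an argmax label
  cannot enter a KL); probabilities are floored at 1e-12.
- **Hierarchy.**  Coarse-class probabilities sum fine-class mass through a
  fixed surjective map; the coarse cross-entropy joins the objective.
- **Deferral.**  θ_t = clip(θ₀ + ε_θ U(t) + ζ Var(ẑ_t), 0, 1); the argmax
  of π is emitted iff max_j π_j ≥ θ (the per-window decision uses the mean
  of θ_t over the window); otherwise the window is deferred and recorded.

Total objective: CE(π, y) + λ₁ L_trust + λ₂ CE(ŷ_coarse, y_coarse), added to
the PGIN loss when trained jointly (the default; a frozen-PGIN mode trains
AHSIM alone).  Defaults λ₁ = 0.1, λ₂ = 0.5.

## Training protocol

Adam, initial learning rate 1e-3 decayed ×0.1 every 10 epochs, batch 64, up
to 100 epochs with early stopping on validation loss (patience 20), dropout
0.3 on the latent path, decoupled weight decay 1e-5, and masked channel
dropout (each channel dropped with probability 0.1 per batch) to emulate
sensor dropout during training.  Validation is always scored with the full
(un-annealed) KL weight so epochs are comparable.  All randomness flows from
a single seed through named substreams.  Because no automatic
differentiation framework is a dependency, the package carries its own
reverse-mode tape over NumPy (`physiograph.autodiff`), with an Adam
implementation and a finite-difference gradient checker; tape gradients are
verified against central differences in the test suite.

Weight initialization is scaled-uniform fan-in, with two deliberate
exceptions: the log-variance head bias starts at −2 (early samples
concentrated, sd ≈ 0.37), and when d_h = d_k the sensor encoders start near
the identity, so the initial edge similarity scores reflect raw inter-channel
signal correlation — the mutual-information view of the dependence kernel —
before training reshapes them.

## Synthetic data: what it emulates and what it does not

The simulator realizes the generative assumptions directly: a geometric-
dwell Markov chain over discrete states (mean dwell `dwell_scale` samples;
the per-sample kernel is recovered at dwell 1), per-(state, sensor) waveform
templates (base level, oscillation frequency, amplitude) with
phase-continuous frequency switching, shared Ornstein–Uhlenbeck drivers
added to coupled channel pairs (the ground-truth graph), and i.i.d. Gaussian
emission noise.  Preprocessing follows the standard wearable pipeline:
linear-interpolation resampling (100 Hz default), 5-s windows with 50 %
overlap (defaults), per-window per-channel z-scoring with a constant-channel
guard, majority window labels with ties to the lower class.  Corruption
implements additive noise (sd 0.1) on retained channels plus masking of
⌊fraction·K⌋ channels; masking order is a seed-determined permutation so
higher fractions mask supersets (nested corruption levels), and masking is
idempotent.

The **reference study conditions** used by the recovery experiments and the
acceptance script: 3 states, 8 sensors (10 for the robustness study, so
masking fractions 0.1/0.2/0.3 remove 1/2/3 channels), states
frequency-coded into disjoint oscillation bands (≈1–4.5, 5.5–9, 10–13.5 Hz
at a 32 Hz rate, each sensor 0.5 Hz apart within the band), amplitude 1,
noise sd 0.1, two coupled pairs (0,1) and (2,3) with driver weight 0.9, mean
dwell 8 s, 2-s windows with 50 % overlap.  Frequency coding matters:
per-window z-scoring removes mean and scale, so states must differ in
waveform shape to remain identifiable — as they do in real rhythmic
physiology.  Training/validation/test splits are independently simulated
recordings (24/2.7/3.3 minutes), which excludes any window-overlap leakage.
A matched-filter (nearest-template) classifier on the known template
frequencies serves as the separability certificate, and pairwise plug-in
mutual information (2-D histogram, 8 bins) as the feasibility baseline for
graph recovery.

What passing these experiments does **not** show: the templates are
surrogates, not morphologically realistic ECG/PPG; emissions are
conditionally Gaussian; context covariates and inter-subject variability
are not emulated (the LOSO machinery is exercised structurally, not
physiologically); and camera-based modalities are out of scope.  Results on
this simulator certify that the implementation recovers the structure it
assumes — not clinical performance.

## Numerical and statistical choices

- Probabilities are clamped at 1e-12 before any logarithm; the z-score
  guard treats channels with sd < 1e-8 as constant (output zeros).
- Sample intervals are 0-based and half-open everywhere.
- Ties: argmax takes the lowest class index; the emit/defer comparison is
  inclusive (emit at equality).
- Deterministic evaluation decodes the posterior mean path; training draws
  one reparameterized sample per step.
- The deferral-rate curve is nondecreasing in θ₀ by construction (the
  per-window confidence is fixed while the threshold rises).
- Chance-level checks on held-out accuracy use an effective sample size
  equal to the number of latent dwell segments (duration / mean dwell), not
  the window count: windows overlap and states persist for many windows, so
  a window-count binomial interval would be badly anti-conservative.  After
  label-shuffled training the model collapses to a label-independent
  predictor, whose accuracy is then compared to 1/|Z| within 3 such standard
  errors.
- AUC is one-vs-rest macro; when a test set lacks classes, AUC is computed
  on the present classes (renormalized) or reported absent for a single
  class — never silently set to 0.

## Known limitations

- The NumPy tape favors clarity over throughput; the reference experiments
  run in minutes on one CPU, but the stack is not sized for hour-scale
  datasets.
- The learned adjacency is an embedding-similarity estimate; it inherits
  the identifiability caveats of correlation-based dependence measures
  (common drivers inflate edges between jointly driven channels).
- The MLP edge kernel is retained for completeness but offers no
  sign-consistency guarantee for graph recovery.
- Deferral thresholds are fixed rules on uncertainty and latent dispersion;
  no cost model of deferral is learned.
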