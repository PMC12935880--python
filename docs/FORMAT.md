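# File formats

## Recording container (HDF5)

One recording per file.  Layout (version `1.0`):

| Path              | Type / shape        | Required | Meaning                                   |
|-------------------|---------------------|----------|-------------------------------------------|
| `/signals`        | float64, (K, T)     | yes      | channel × sample matrix, finite values    |
| `/labels`         | int64, (T,)         | no       | per-sample class; absent ⇒ inference-only |
| `/context`        | float64, (T, d_c)   | no       | per-sample context covariates             |
| `/truth/states`   | int64, (T,)         | no       | synthetic ground-truth latent states      |
| `/truth/coupling` | float64, (K, K)     | no       | symmetric, zero-diagonal coupling weights |

Root attributes: `sample_rate` (Hz, float), `format_version` (str),
`subject` (str), `channel_names`, `channel_modalities`, `channel_units`,
`channel_masked` (length-K lists).

Labels may alternatively travel as CSV with columns
`sample_index,label` (0-based sample indices).

## Checkpoints (HDF5)

Groups `pgin/`, `heads/`, `ahsim/` hold one float64 dataset per parameter
array, named after the parameter field.  Group attributes carry the
structural hyperparameters (dims, activation, edge kernel, adjacency mode,
loss weights, thresholds); `ahsim` additionally stores `risk_priors`, `s0`
and the hierarchy map as JSON.  Root attributes: `format_version`,
`n_classes`.

## Run directories

`physiograph train --out RUN` writes:

- `config.json` — resolved configuration with per-key provenance
  (`default` vs `user`) and the seed;
- `history.jsonl` — one JSON object per epoch with every loss component
  (`train_ce`, `train_kl`, `train_smoothness`, `train_ahsim_*`), learning
  rate, validation loss and accuracy;
- `checkpoint.h5` — best-validation parameters;
- `predictions_val.csv` — per-window class probabilities, `y_pred`,
  `mean_U`, `theta`, `emitted`, `label`.

`eval` adds `metrics.json` and `predictions_eval.csv`; `explain` writes a
directory with `trace.csv` (per-step U, η, α, δ, θ, evidence s, decoder
probabilities, latent coordinates), `adjacency.csv` (subsampled t, i, j,
weight heatmap data) and `decision.json` (π, final/coarse prediction,
aggregate uncertainty, emit/defer record).

## Configuration (YAML or JSON)

Top-level sections `sim`, `model`, `train`, `ahsim`, `eval` plus `seed`.
Unknown keys are rejected with a nearest-key suggestion.  Defaults follow
the documented training protocol (lr 1e-3 with ×0.1 decay every 10 epochs,
batch 64, ≤100 epochs, patience 20, dropout 0.3, weight decay 1e-5, 5-s
windows, 50 % overlap, 100 Hz).
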