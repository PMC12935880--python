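"""Generator, dependence kernel, preprocessing and corruption behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physiograph import synthgen
from physiograph.synthgen import (
    AugmentConfig,
    SimConfig,
    augment,
    corrupt,
    emit_signals,
    mi_kernel,
    preprocess_and_window,
    sample_latent_path,
    simulate_recording,
    template_trajectory,
)


def _cfg(**kw):
    defaults = dict(
        n_sensors=2,
        n_states=2,
        transition_matrix=np.array([[0.5, 0.5], [0.5, 0.5]]),
        emission_templates=np.zeros((2, 2, 3)),
        noise_sd=0.0,
        sample_rate=10.0,
        duration=10.0,
        dwell_scale=1.0,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestLatentPath:
    def test_identity_transition_is_absorbing(self):
        cfg = _cfg(transition_matrix=np.eye(2), duration=50.0)
        states = sample_latent_path(cfg)
        assert len(np.unique(states)) == 1

    def test_permutation_matrix_alternates(self):
        cfg = _cfg(transition_matrix=np.array([[0.0, 1.0], [1.0, 0.0]]), duration=20.0)
        states = sample_latent_path(cfg)
        assert np.all(states[1:] != states[:-1])

    def test_stationary_frequency_matches_eigen_oracle(self):
        # chain-aware standard error: var factor (1 + lam2) / (1 - lam2)
        p = 0.3
        cfg = _cfg(
            transition_matrix=np.array([[1 - p, p], [p, 1 - p]]),
            sample_rate=100.0,
            duration=1000.0,  # T = 100000
        )
        states = sample_latent_path(cfg)
        T_mat = cfg.transition_matrix
        evals, evecs = np.linalg.eig(T_mat.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = pi / pi.sum()
        lam2 = sorted(np.abs(np.real(evals)))[0]
        freq1 = (states == 0).mean()
        se = np.sqrt(pi[0] * (1 - pi[0]) * (1 + lam2) / (1 - lam2) / len(states))
        assert abs(freq1 - pi[0]) < 3 * se

    def test_empirical_transition_matrix_converges(self):
        T_true = np.array([[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.25, 0.25, 0.5]])
        cfg = _cfg(
            n_states=3,
            n_sensors=2,
            transition_matrix=T_true,
            emission_templates=np.zeros((3, 2, 3)),
            sample_rate=100.0,
            duration=1000.0,
        )
        states = sample_latent_path(cfg)
        counts = np.zeros((3, 3))
        np.add.at(counts, (states[:-1], states[1:]), 1)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(emp - T_true).max() < 0.02

    def test_non_stochastic_row_rejected_with_row_index(self):
        with pytest.raises(ValueError, match="row"):
            _cfg(transition_matrix=np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_dwell_scale_lengthens_runs(self):
        short = sample_latent_path(_cfg(duration=200.0, seed=5))
        long = sample_latent_path(_cfg(duration=200.0, dwell_scale=20.0, seed=5))
        runs = lambda s: len(s) / max((s[1:] != s[:-1]).sum(), 1)
        assert runs(long) > 4 * runs(short)

    def test_reproducible_given_seed(self):
        cfg = _cfg(seed=9)
        assert np.array_equal(sample_latent_path(cfg), sample_latent_path(cfg))


class TestEmission:
    def test_zero_noise_equals_template_trajectory(self):
        tpl = np.zeros((2, 2, 3))
        tpl[:, :, 0] = [[0.0, 1.0], [2.0, 3.0]]
        tpl[:, :, 1] = 1.5
        tpl[:, :, 2] = 0.7
        cfg = _cfg(emission_templates=tpl)
        states = sample_latent_path(cfg)
        rec = emit_signals(states, cfg)
        assert np.array_equal(rec.signals, template_trajectory(states, cfg))
        assert np.array_equal(rec.labels, states)
        assert rec.truth_coupling.sum() == 0

    def test_noise_sd_recovered_on_constant_template(self):
        cfg = _cfg(noise_sd=0.1, sample_rate=100.0, duration=1000.0)  # T = 100000
        states = np.zeros(cfg.n_samples, dtype=int)
        rec = emit_signals(states, cfg)
        sd = rec.signals.std(axis=1)
        se = 0.1 / np.sqrt(2 * (cfg.n_samples - 1))
        assert np.all(np.abs(sd - 0.1) < 3 * se)

    def test_full_weight_coupling_identical_channels(self):
        cfg = _cfg(coupling_edges=((0, 1, 1.0),))
        states = sample_latent_path(cfg)
        rec = emit_signals(states, cfg)
        assert np.array_equal(rec.signals[0], rec.signals[1])
        assert rec.truth_coupling[0, 1] == 1.0 and rec.truth_coupling[1, 0] == 1.0

    def test_invalid_state_label_rejected(self):
        cfg = _cfg()
        with pytest.raises(ValueError, match="template"):
            emit_signals(np.array([0, 1, 5]), cfg)


class TestMiKernel:
    def test_perfect_binary_dependence_is_ln2(self):
        x = np.tile([0.0, 1.0], 500)
        assert mi_kernel(x, x, n_bins=2) == pytest.approx(np.log(2), abs=1e-12)

    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 100000))
        assert mi_kernel(x, y, n_bins=8) < 0.01

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 200))
        assert mi_kernel(x, y) == pytest.approx(mi_kernel(y, x), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mi_kernel(np.zeros(5), np.zeros(6))

    def test_coupled_pairs_exceed_uncoupled_on_average(self):
        mis_c, mis_u = [], []
        for seed in range(50):
            cfg = synthgen.default_sim_config(seed=seed, duration=10.0)
            rec = simulate_recording(cfg)
            mis_c.append(mi_kernel(rec.signals[0], rec.signals[1]))
            mis_u.append(mi_kernel(rec.signals[0], rec.signals[4]))
        assert np.mean(mis_c) > np.mean(mis_u)


class TestCorrupt:
    def test_identity_when_disabled(self, small_sim_config):
        rec = simulate_recording(small_sim_config)
        out = corrupt(rec, noise_sd=0.0, mask_fraction=0.0)
        assert np.array_equal(out.signals, rec.signals)
        assert np.array_equal(out.labels, rec.labels)

    def test_full_masking_flags_all_channels(self, small_sim_config):
        rec = simulate_recording(small_sim_config)
        out = corrupt(rec, mask_fraction=1.0)
        assert out.masked_channels.all()
        assert np.all(out.signals == 0)

    def test_floor_arithmetic(self):
        tpl = np.zeros((2, 10, 3))
        cfg = _cfg(n_sensors=10, emission_templates=tpl)
        rec = simulate_recording(cfg)
        out = corrupt(rec, mask_fraction=0.3, seed=4)
        assert out.masked_channels.sum() == 3

    def test_masking_nested_and_idempotent(self, small_sim_config):
        rec = simulate_recording(small_sim_config)
        lo = corrupt(rec, mask_fraction=0.25, seed=11)
        hi = corrupt(rec, mask_fraction=0.5, seed=11)
        assert set(np.where(lo.masked_channels)[0]) <= set(np.where(hi.masked_channels)[0])
        again = corrupt(lo, mask_fraction=0.25, seed=11)
        assert np.array_equal(again.masked_channels, lo.masked_channels)
        assert np.array_equal(again.signals[lo.masked_channels], lo.signals[lo.masked_channels])

    def test_noise_preserves_labels_and_shapes(self, small_sim_config):
        rec = simulate_recording(small_sim_config)
        out = corrupt(rec, noise_sd=0.2, seed=1)
        assert out.signals.shape == rec.signals.shape
        assert np.array_equal(out.labels, rec.labels)

    def test_invalid_fraction_rejected(self, small_sim_config):
        rec = simulate_recording(small_sim_config)
        with pytest.raises(ValueError):
            corrupt(rec, mask_fraction=1.5)


class TestPreprocessAndWindow:
    def test_stride_arithmetic(self):
        rec = synthgen.SensorRecording(
            signals=np.random.default_rng(0).normal(size=(2, 1000)),
            sample_rate=100.0,
            labels=np.zeros(1000, dtype=int),
        )
        batch = preprocess_and_window(rec, 100.0, 5.0, 0.5)
        assert batch.n_windows == 3
        assert np.array_equal(batch.intervals[:, 0], [0, 250, 500])
        assert batch.window_length == 500

    def test_window_count_formula(self):
        for T in (64, 100, 129, 500, 731):
            rec = synthgen.SensorRecording(
                signals=np.random.default_rng(T).normal(size=(2, T)),
                sample_rate=32.0,
            )
            batch = preprocess_and_window(rec, 32.0, 1.0, 0.5)
            L, stride = 32, 16
            expected = max((T - L) // stride + 1, 0)
            assert batch.n_windows == expected

    def test_constant_channel_guarded(self):
        sig = np.vstack([np.ones(300), np.random.default_rng(1).normal(size=300)])
        rec = synthgen.SensorRecording(signals=sig, sample_rate=100.0)
        batch = preprocess_and_window(rec, 100.0, 1.0)
        assert np.all(batch.windows[:, 0, :] == 0)
        assert np.all(np.isfinite(batch.windows))

    def test_zscore_within_tolerance(self, small_batch):
        means = small_batch.windows.mean(axis=2)
        sds = small_batch.windows.std(axis=2)
        assert np.abs(means).max() < 1e-6
        nonconstant = sds > 0.5
        assert np.abs(sds[nonconstant] - 1.0).max() < 1e-6

    def test_identity_resample_preserves_values(self):
        sig = np.random.default_rng(2).normal(size=(2, 200))
        rec = synthgen.SensorRecording(signals=sig, sample_rate=50.0)
        batch = preprocess_and_window(rec, 50.0, 1.0, 0.0)
        # window 0 must be the z-score of the raw samples, bit-for-bit
        w = sig[:, :50]
        expected = (w - w.mean(axis=1, keepdims=True)) / w.std(axis=1, keepdims=True)
        assert np.array_equal(batch.windows[0], expected)

    def test_resampling_changes_rate(self):
        sig = np.sin(np.linspace(0, 20 * np.pi, 640))[None, :].repeat(2, axis=0)
        rec = synthgen.SensorRecording(signals=sig, sample_rate=64.0, labels=np.zeros(640, int))
        batch = preprocess_and_window(rec, 32.0, 2.0)
        assert batch.window_length == 64
        assert batch.sample_rate == 32.0

    def test_short_recording_empty_batch(self, caplog):
        rec = synthgen.SensorRecording(signals=np.zeros((2, 10)), sample_rate=100.0)
        import logging

        with caplog.at_level(logging.WARNING):
            batch = preprocess_and_window(rec, 100.0, 5.0)
        assert batch.n_windows == 0
        assert any("shorter" in r.message for r in caplog.records)

    def test_majority_label_tie_breaks_low(self):
        labels = np.array([1] * 25 + [0] * 25)
        rec = synthgen.SensorRecording(
            signals=np.random.default_rng(3).normal(size=(2, 50)),
            sample_rate=50.0,
            labels=labels,
        )
        batch = preprocess_and_window(rec, 50.0, 1.0)
        assert batch.window_labels[0] == 0


class TestAugment:
    def test_all_probabilities_zero_is_identity(self, small_batch):
        out = augment(small_batch, AugmentConfig(), seed=0)
        assert np.array_equal(out.windows, small_batch.windows)
        assert np.array_equal(out.window_labels, small_batch.window_labels)

    def test_unit_crop_fraction_is_identity(self, small_batch):
        cfg = AugmentConfig(crop_prob=1.0, crop_fraction=1.0)
        out = augment(small_batch, cfg, seed=0)
        assert np.array_equal(out.windows, small_batch.windows)

    def test_deterministic_under_seed(self, small_batch):
        cfg = AugmentConfig(noise_prob=1.0, crop_prob=0.5, warp_prob=0.5)
        a = augment(small_batch, cfg, seed=7)
        b = augment(small_batch, cfg, seed=7)
        assert np.array_equal(a.windows, b.windows)
        assert not np.array_equal(a.windows, small_batch.windows)

    def test_invalid_crop_fraction_rejected(self, small_batch):
        with pytest.raises(ValueError):
            augment(small_batch, AugmentConfig(crop_prob=1.0, crop_fraction=0.0), seed=0)

    def test_warp_preserves_shape_and_labels(self, small_batch):
        cfg = AugmentConfig(warp_prob=1.0, warp_strength=0.2)
        out = augment(small_batch, cfg, seed=3)
        assert out.windows.shape == small_batch.windows.shape
        assert np.array_equal(out.window_labels, small_batch.window_labels)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        _cfg(n_sensors=1)
    with pytest.raises(ValueError):
        _cfg(noise_sd=-0.1)
    with pytest.raises(ValueError):
        _cfg(coupling_edges=((0, 1, 1.5),))
    cfg = _cfg()
    rec = simulate_recording(cfg)
    assert np.all(np.isfinite(rec.signals))
    assert len(rec.labels) == rec.n_samples
    C = rec.truth_coupling
    assert np.allclose(C, C.T) and np.all(np.diag(C) == 0)
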