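"""Synthetic generator: duty cycle, Markov structure, determinism, regimes."""

import dataclasses

import numpy as np
import pytest

from patchsleep.config import (
    BLOCK_DURATION_S,
    BLOCK_PERIOD_S,
    ConfigurationError,
    SimulationConfig,
)
from patchsleep.preprocess import process_ecg_block
from patchsleep.simulate import (
    cohort_manifest,
    derive_seed,
    simulate_acc_stream,
    simulate_ecg_stream,
    simulate_hypnogram,
    simulate_session,
    stationary_distribution,
)


@pytest.fixture(scope="module")
def short_cfg():
    return SimulationConfig(night_duration=60.0)


class TestHypnogram:
    def test_epoch_count_matches_night_duration(self):
        cfg = SimulationConfig(night_duration=480.0)
        hyp = simulate_hypnogram(cfg, 0)
        assert len(hyp) == 960  # 480 min * 60 / 30 s

    def test_identity_matrix_keeps_chain_in_wake(self):
        cfg = SimulationConfig(
            night_duration=60.0, stage_transition_matrix=np.eye(5)
        )
        hyp = simulate_hypnogram(cfg, 3)
        assert set(hyp.stages) == {"W"}

    def test_nonstochastic_matrix_rejected(self):
        m = np.eye(5)
        m[0, 0] = 0.5
        with pytest.raises(ConfigurationError):
            SimulationConfig(stage_transition_matrix=m)

    def test_empirical_frequencies_approach_stationary_distribution(self):
        cfg = SimulationConfig(night_duration=5000.0)  # 10,000 epochs
        hyp = simulate_hypnogram(cfg, 12)
        pi = stationary_distribution(cfg.stage_transition_matrix)
        counts = np.array(
            [sum(s == st for s in hyp.stages) for st in ("W", "N1", "N2", "N3", "R")]
        )
        freq = counts / len(hyp)
        # autocorrelation-corrected standard error from the chain's spectral gap
        lam = np.sort(np.abs(np.linalg.eigvals(cfg.stage_transition_matrix)))[-2]
        n_eff = len(hyp) * (1 - lam) / (1 + lam)
        se = np.sqrt(pi * (1 - pi) / n_eff)
        assert np.all(np.abs(freq - pi) <= 3 * se + 1e-12)

    def test_deterministic_given_seed(self, short_cfg):
        assert simulate_hypnogram(short_cfg, 7).stages == simulate_hypnogram(short_cfg, 7).stages


class TestDutyCycle:
    def test_block_grid_and_duration(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, acc_dropout_rate=0.0)
        hyp = simulate_hypnogram(cfg, 1)
        for stream, rate in [
            (simulate_acc_stream(hyp, cfg, 2), cfg.acc_sampling_rate),
            (simulate_ecg_stream(hyp, cfg, 2), cfg.ecg_sampling_rate),
        ]:
            starts = np.array([b.start_time for b in stream])
            assert np.allclose(np.diff(starts), BLOCK_PERIOD_S)
            for b in stream:
                n = b.samples.shape[0]
                assert abs(n - BLOCK_DURATION_S * rate) <= 1

    def test_three_blocks_begin_in_any_minute(self, short_cfg):
        cfg = dataclasses.replace(short_cfg, acc_dropout_rate=0.0)
        hyp = simulate_hypnogram(cfg, 1)
        starts = np.array([b.start_time for b in simulate_acc_stream(hyp, cfg, 5)])
        for t0 in (0.0, 60.0, 120.0, 737.0):
            if t0 + 60 <= hyp.duration_s:
                assert np.sum((starts >= t0) & (starts < t0 + 60.0)) == 3


class TestAccStream:
    def test_noiseless_static_posture_equals_gravity(self):
        cfg = SimulationConfig(
            night_duration=10.0,
            acc_noise_sd=0.0,
            acc_dropout_rate=0.0,
            posture_shift_rate=0.0,
            movement_burst_rate_by_state={"wake": 0.0, "sleep": 0.0},
        )
        hyp = simulate_hypnogram(cfg, 0)
        blocks = simulate_acc_stream(hyp, cfg, 9)
        g = blocks[0].samples[0]
        assert np.isclose(np.linalg.norm(g), 1.0)
        for b in blocks:
            assert np.allclose(b.samples, g)

    def test_wake_movement_exceeds_sleep_movement(self):
        # half-wake, half-sleep night; wake bursts dominate block variance
        cfg = SimulationConfig(night_duration=60.0, acc_dropout_rate=0.0)
        from patchsleep.session import Hypnogram

        stages = ("W",) * 60 + ("N2",) * 60
        hyp = Hypnogram(stages)
        wake_var, sleep_var = [], []
        for seed in range(5):
            for b in simulate_acc_stream(hyp, cfg, seed):
                mag = np.linalg.norm(b.samples, axis=1)
                (wake_var if b.start_time < 1800 else sleep_var).append(mag.var())
        assert np.mean(wake_var) > np.mean(sleep_var)


class TestEcgStream:
    def test_clean_block_rr_matches_configured_hr(self, filter_spec):
        cfg = SimulationConfig(
            night_duration=10.0,
            hr_mean_by_state={"wake": 60.0, "sleep": 60.0},
            hr_sd=0.0,
            rr_jitter=0.0,
            ecg_noise_sd=0.0,
            contact_dropout_transition=np.array([[1.0, 0.0], [1.0, 0.0]]),
        )
        hyp = simulate_hypnogram(cfg, 0)
        block = simulate_ecg_stream(hyp, cfg, 4)[0]
        feats = process_ecg_block(block, filter_spec)
        assert feats.rr_vector.size >= 10
        assert abs(np.mean(feats.rr_vector) - 1.0) <= 2.0 / cfg.ecg_sampling_rate

    def test_permanent_bad_contact_fails_all_validity(self, filter_spec):
        cfg = SimulationConfig(
            night_duration=20.0,
            contact_dropout_transition=np.array([[0.0, 1.0], [0.0, 1.0]]),
        )
        hyp = simulate_hypnogram(cfg, 0)
        blocks = simulate_ecg_stream(hyp, cfg, 4)
        # chain enters (and stays in) bad contact from the second block on
        assert all(not process_ecg_block(b, filter_spec).valid for b in blocks[1:])

    def test_default_contact_regime_usability(self, filter_spec):
        # target regime: ~73% of ECG blocks usable (+-10 percentage points)
        cfg = SimulationConfig()
        valid = total = 0
        for night in range(2):
            sess = simulate_session(cfg, f"P{night}", night, night)
            for b in sess.ecg_blocks:
                valid += process_ecg_block(b, filter_spec).valid
                total += 1
        assert abs(valid / total - 0.73) <= 0.10


class TestCohort:
    def test_manifest_counts_and_smi_tagging(self):
        cfg = SimulationConfig(n_participants=60, smi_fraction=35 / 60)
        m = cohort_manifest(cfg)
        assert len(m.participants) == 60
        assert sum(1 for _, g in m.participants if g == "SMI") == 35
        assert len({p for p, _ in m.participants}) == 60

    def test_same_seed_reproduces_bytes(self):
        cfg = SimulationConfig(n_participants=2, night_duration=20.0)
        a = simulate_session(cfg, "P001", 0, 0)
        b = simulate_session(cfg, "P001", 0, 0)
        assert a.hypnogram.stages == b.hypnogram.stages
        assert all(
            np.array_equal(x.samples, y.samples)
            for x, y in zip(a.acc_blocks, b.acc_blocks)
        )
        assert all(
            np.array_equal(x.samples, y.samples)
            for x, y in zip(a.ecg_blocks, b.ecg_blocks)
        )
        assert cohort_manifest(cfg).to_json() == cohort_manifest(cfg).to_json()

    def test_derived_seeds_distinct_per_stream(self):
        seeds = {derive_seed(0, p, n, s) for p in range(3) for n in range(2) for s in range(3)}
        assert len(seeds) == 18


class TestRegimes:
    def test_sleep_window_balance_over_20_nights(self):
        # aggregate fraction of sleep-labeled 5-min windows in [0.75, 0.92]
        cfg = SimulationConfig()
        sleep = total = 0
        for s in range(20):
            hyp = simulate_hypnogram(cfg, 500 + s)
            wake = np.array([st == "W" for st in hyp.stages], dtype=int)
            nw = len(wake) // 10
            wake_counts = wake[: nw * 10].reshape(nw, 10).sum(axis=1)
            sleep += int(np.sum(wake_counts < 5))
            total += nw
        assert 0.75 <= sleep / total <= 0.92

    def test_state_dependent_heart_rate_direction(self, small_cohort):
        hr_sleep, hr_wake = [], []
        for _, night in small_cohort:
            for w in night.valid_windows:
                (hr_sleep if w.psg_label == "sleep" else hr_wake).append(
                    w.ecg_block.mean_hr
                )
        assert np.mean(hr_wake) > np.mean(hr_sleep)
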