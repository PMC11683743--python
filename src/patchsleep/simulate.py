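"""Synthetic cohort generator.

Emulates the study regime the pipeline was designed for: overnight lab
sessions in which a torso patch records 14 s of tri-axial acceleration and
single-lead ECG in every 20-s interval while PSG is scored in 30-s epochs.
Sleep structure is a first-order Markov chain over the five PSG stages;
movement and heart rate depend on the binary sleep/wake state; ECG contact
quality follows a two-state chain that intermittently drowns the signal in
noise, so that roughly a quarter of ECG blocks fail downstream validity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import (
    BLOCK_DURATION_S,
    BLOCK_PERIOD_S,
    STAGES,
    SLEEP_STAGES,
    ConfigurationError,
    SimulationConfig,
)
from .session import AccBlock, EcgBlock, Hypnogram, SessionRecording

__all__ = [
    "simulate_hypnogram",
    "simulate_acc_stream",
    "simulate_ecg_stream",
    "simulate_session",
    "simulate_cohort",
    "iter_cohort_sessions",
    "cohort_manifest",
    "CohortManifest",
    "stationary_distribution",
    "derive_seed",
]


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed for a (participant, night, stream) tuple."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(matrix.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    return v / v.sum()


def simulate_hypnogram(config: SimulationConfig, participant_seed: int) -> Hypnogram:
    """Draw one night of 30-s stages from the configured Markov chain.

    The chain starts in wake (lights-off at the start of recording) and runs
    for ``night_duration`` minutes.
    """
    m = config.stage_transition_matrix
    rng = np.random.default_rng(participant_seed)
    n = config.n_epochs
    cdf = np.cumsum(m, axis=1)
    states = np.empty(n, dtype=np.int64)
    state = 0  # W
    for i in range(n):
        states[i] = state
        state = int(np.searchsorted(cdf[state], rng.random(), side="right"))
    return Hypnogram(tuple(STAGES[s] for s in states), config.epoch_duration)


def _block_starts(hypnogram: Hypnogram) -> np.ndarray:
    n_blocks = int(hypnogram.duration_s // BLOCK_PERIOD_S)
    return np.arange(n_blocks) * BLOCK_PERIOD_S


def _is_sleep(stage: str) -> bool:
    return stage in SLEEP_STAGES


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_acc_stream(
    hypnogram: Hypnogram, config: SimulationConfig, seed: int
) -> list[AccBlock]:
    """Generate the duty-cycled tri-axial acceleration stream for one night.

    Gravity follows a piecewise-constant posture orientation with Poisson
    shift events; movement appears as short oscillatory bursts at the step
    cadence along the gravity axis (vertical body motion), at a state-
    dependent rate; white noise is added per axis. A small per-block dropout
    probability emulates occasional lost ACC blocks.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    rng = np.random.default_rng(seed)
    rate = config.acc_sampling_rate
    n_samp = int(round(BLOCK_DURATION_S * rate))
    rel_t = np.arange(n_samp) / rate

    # posture schedule over the whole night
    duration = hypnogram.duration_s
    n_shifts = rng.poisson(config.posture_shift_rate * duration / 3600.0)
    shift_times = np.sort(rng.uniform(0.0, duration, size=n_shifts))
    orientations = [_random_unit_vector(rng) for _ in range(n_shifts + 1)]

    blocks: list[AccBlock] = []
    for t0 in _block_starts(hypnogram):
        dropped = rng.random() < config.acc_dropout_rate
        stage = hypnogram.stage_at(t0)
        state = "sleep" if _is_sleep(stage) else "wake"
        posture_idx = int(np.searchsorted(shift_times, t0, side="right"))
        gravity = orientations[posture_idx]
        samples = np.tile(gravity, (n_samp, 1))

        burst_rate = config.movement_burst_rate_by_state[state]  # per minute
        n_bursts = rng.poisson(burst_rate * BLOCK_DURATION_S / 60.0)
        for _ in range(n_bursts):
            b0 = rng.uniform(0.0, BLOCK_DURATION_S - config.burst_duration)
            in_burst = (rel_t >= b0) & (rel_t < b0 + config.burst_duration)
            osc = config.burst_amplitude * np.sin(
                2.0 * np.pi * config.step_cadence * (rel_t[in_burst] - b0)
            )
            samples[in_burst] += osc[:, None] * gravity

        if config.acc_noise_sd > 0:
            samples = samples + rng.normal(0.0, config.acc_noise_sd, size=samples.shape)
        if not dropped:
            blocks.append(AccBlock(float(t0), rate, samples))
    return blocks


def simulate_ecg_stream(
    hypnogram: Hypnogram, config: SimulationConfig, seed: int
) -> list[EcgBlock]:
    """Generate the duty-cycled single-lead ECG stream for one night.

    Each block carries a train of Gaussian-shaped R-peaks whose R-R interval
    is drawn around 60 / hr_mean for the current sleep/wake state. A two-state
    contact-quality chain switches the additive noise between a clean and a
    degraded amplitude; degraded blocks are meant to fail the downstream
    signal-quality test.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    for state, hr in config.hr_mean_by_state.items():
        if not 30.0 < hr < 200.0:
            raise ConfigurationError(f"hr_mean_by_state[{state!r}] outside (30, 200)")
    rng = np.random.default_rng(seed)
    rate = config.ecg_sampling_rate
    n_samp = int(round(BLOCK_DURATION_S * rate))
    sigma = config.r_peak_width
    half_width = int(np.ceil(5 * sigma * rate))
    kernel_t = np.arange(-half_width, half_width + 1) / rate
    kernel = config.r_peak_amplitude * np.exp(-0.5 * (kernel_t / sigma) ** 2)

    contact_cdf = np.cumsum(config.contact_dropout_transition, axis=1)
    contact = 0  # start in good contact

    blocks: list[EcgBlock] = []
    for t0 in _block_starts(hypnogram):
        stage = hypnogram.stage_at(t0)
        state = "sleep" if _is_sleep(stage) else "wake"
        hr = config.hr_mean_by_state[state]
        if config.hr_sd > 0:
            hr = float(np.clip(hr + rng.normal(0.0, config.hr_sd), 35.0, 195.0))
        rr = 60.0 / hr

        # R-peak times within the block
        t = rng.uniform(0.0, rr)
        peak_times = []
        while t < BLOCK_DURATION_S:
            peak_times.append(t)
            step = rr * (1.0 + rng.normal(0.0, config.rr_jitter)) if config.rr_jitter > 0 else rr
            t += max(step, 0.25)

        samples = np.zeros(n_samp)
        for tp in peak_times:
            center = int(round(tp * rate))
            lo = max(0, center - half_width)
            hi = min(n_samp, center + half_width + 1)
            samples[lo:hi] += kernel[lo - (center - half_width) : hi - (center - half_width)]

        noise_sd = (
            config.ecg_noise_sd if contact == 0 else config.ecg_bad_contact_noise_sd
        )
        if noise_sd > 0:
            samples = samples + rng.normal(0.0, noise_sd, size=n_samp)
        blocks.append(EcgBlock(float(t0), rate, samples))

        contact = int(np.searchsorted(contact_cdf[contact], rng.random(), side="right"))
    return blocks


def simulate_session(
    config: SimulationConfig, participant: str, night: int, p_idx: int
) -> SessionRecording:
    """Simulate one participant-night with sub-seeds derived from the master seed."""
    hyp_seed = derive_seed(config.seed, p_idx, night, 0)
    acc_seed = derive_seed(config.seed, p_idx, night, 1)
    ecg_seed = derive_seed(config.seed, p_idx, night, 2)
    hyp = simulate_hypnogram(config, hyp_seed)
    return SessionRecording(
        participant=participant,
        night=night,
        hypnogram=hyp,
        acc_blocks=simulate_acc_stream(hyp, config, acc_seed),
        ecg_blocks=simulate_ecg_stream(hyp, config, ecg_seed),
    )


@dataclass(frozen=True)
class CohortManifest:
    """Cohort roster: participant ids, group tags, per-night references."""

    participants: tuple[tuple[str, str], ...]  # (id, "SMI" | "HV")
    sessions: tuple[dict, ...]
    config: dict
    seed: int

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.participants]
        if len(ids) != len(set(ids)):
            raise ValueError("participant ids must be unique")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "participants": [list(p) for p in self.participants],
                "sessions": list(self.sessions),
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def cohort_manifest(config: SimulationConfig) -> CohortManifest:
    """Roster of the cohort a config describes, without generating signals."""
    n_smi = int(round(config.smi_fraction * config.n_participants))
    participants = tuple(
        (f"P{idx + 1:03d}", "SMI" if idx < n_smi else "HV")
        for idx in range(config.n_participants)
    )
    sessions = tuple(
        {
            "participant": pid,
            "group": group,
            "night": night,
            "p_idx": idx,
        }
        for idx, (pid, group) in enumerate(participants)
        for night in range(config.nights_per_participant)
    )
    return CohortManifest(participants, sessions, config.to_dict(), config.seed)


def iter_cohort_sessions(config: SimulationConfig):
    """Yield ``(group, SessionRecording)`` for every participant-night, in order."""
    manifest = cohort_manifest(config)
    for entry in manifest.sessions:
        yield entry["group"], simulate_session(
            config, entry["participant"], entry["night"], entry["p_idx"]
        )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortManifest:
    """Write a full cohort to disk as per-night CSVs plus ``manifest.json``.

    Layout: ``<out>/<participant>/night<k>/{acc,ecg,psg}.csv``. Refuses to
    overwrite an existing manifest so that runs cannot silently collide.
    """
    from .io import write_session  # local import to avoid a cycle

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise FileExistsError(f"output path collision: {manifest_path} exists")
    out.mkdir(parents=True, exist_ok=True)

    manifest = cohort_manifest(config)
    sessions = []
    for entry in manifest.sessions:
        session = simulate_session(
            config, entry["participant"], entry["night"], entry["p_idx"]
        )
        night_dir = out / entry["participant"] / f"night{entry['night']}"
        write_session(session, night_dir)
        sessions.append({**entry, "path": str(night_dir.relative_to(out))})
    manifest = CohortManifest(
        manifest.participants, tuple(sessions), manifest.config, manifest.seed
    )
    manifest_path.write_text(manifest.to_json())
    return manifest
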