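"""Synthetic tongue motor-imagery EEG study generator.

Emulates the offline study design that the analysis pipeline assumes:
15 subjects x 3 movement patterns x 2 sessions x 24 trials, each trial a
5 s baseline / 5 s execution / 5 s imagery sequence at 256 Hz on the
fixed 14-channel montage.

Each channel is a sum of four processes:

* **1/f background** — spectrally shaped Gaussian noise (exponent
  configurable, default 1), the standard broadband EEG floor;
* **alpha rhythm** — a narrowband stochastic oscillator (white noise
  band-limited to 10-12 Hz), so event-related desynchronization (ERD)
  is amplitude modulation of a rhythm with real bandwidth rather than a
  sinusoid;
* **50 Hz line interference** — a sinusoid with a per-trial random
  phase, common across channels;
* **white sensor noise**.

During execution and imagery the alpha amplitude on channel *i* is
scaled by ``sqrt(1 - w_i * g * E / 100)`` (template weight ``w_i``,
subject effect gain ``g``, nominal ERD percent ``E``), so alpha *power*
drops by exactly the configured ERD fraction.

Command topographies follow the contralateral frontal-central
organization of imagined lateral tongue movements: left-side imagery
peaks on right-hemisphere FC6 (and mirror for right-side), cheek-bulge
imagery is a stronger version of corner imagery, and the vertical lip
tasks are bilateral, with the lower-lip map more spatially widespread
and configurably overlapping the upper-lip map.

Inter-subject variability (the dominant feature of real motor-imagery
EEG) enters through per-subject effect gains, per-channel amplitude and
topography jitter, all drawn from a seeded hierarchy so every study is
reproducible end-to-end from one master seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

from .io import (COMMANDS, MIRROR_PAIRS, PATTERNS, ChannelSet, RawRecording,
                 command_pattern, standard_montage)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopographyTemplate:
    """Per-channel ERD weights (fractions of the nominal magnitude)."""

    command: str
    weights: np.ndarray  # (14,), each in [0, 1], montage order

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (14,) or np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must be 14 values in [0, 1]")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal amplitudes and effect-size variability."""

    subject_id: str
    alpha_amplitude: np.ndarray      # (14,) µV RMS of the alpha process
    background_scale: float          # µV RMS of the 1/f background
    line_amplitude: float            # µV amplitude of the 50 Hz sinusoid
    effect_gain: float               # multiplies the nominal ERD fraction
    topography_jitter: np.ndarray    # (14,) multiplicative weight noise
    rng_seed: int

    def __post_init__(self) -> None:
        if np.any(self.alpha_amplitude < 0) or self.background_scale < 0 \
                or self.line_amplitude < 0 or self.effect_gain < 0:
            raise ValueError("amplitudes and effect_gain must be >= 0")


def _default_erd() -> dict[str, float]:
    return {"LL": 30.0, "LR": 30.0, "CL": 40.0, "CR": 40.0,
            "LU": 35.0, "LD": 25.0}


@dataclass
class SimulationConfig:
    """Study-design and signal-model parameters (units in docstrings).

    Defaults reproduce the study layout: 15 subjects, 12 trials per
    command per session, 2 sessions per pattern, 3 patterns -> 144
    trials per subject, 2160 trials total.  Nominal ERD magnitudes are
    ordered cheek > lip-up > corner > lip-down, matching the observed
    ordering of imagined-effort strength and LD's weakest
    discriminability.
    """

    n_subjects: int = 15
    trials_per_command_per_session: int = 12
    sessions_per_pattern: int = 2
    baseline_s: float = 5.0
    execution_s: float = 5.0
    imagery_s: float = 5.0
    fs: float = 256.0
    nominal_erd_percent: dict[str, float] = field(default_factory=_default_erd)
    alpha_band: tuple[float, float] = (10.0, 12.0)
    # amplitude hyper-parameters (µV RMS / coefficient of variation)
    alpha_amplitude_mean: float = 10.0
    alpha_amplitude_cv: float = 0.2
    occipital_alpha_gain: float = 1.5
    background_scale_mean: float = 4.0
    background_scale_cv: float = 0.2
    background_exponent: float = 1.0
    line_freq: float = 50.0
    line_amplitude_mean: float = 2.0
    line_amplitude_cv: float = 0.3
    sensor_noise_uv: float = 1.0
    # inter-subject variability
    effect_gain_sd: float = 0.2
    topography_jitter_sd: float = 0.1
    # fraction of the upper-lip template mixed into the lower-lip one
    lu_ld_overlap: float = 0.3
    seed: int = 0

    @property
    def trials_per_subject(self) -> int:
        return (self.trials_per_command_per_session * 2
                * self.sessions_per_pattern * len(PATTERNS))

    @property
    def trial_samples(self) -> tuple[int, int, int]:
        """(baseline, execution, imagery) lengths in samples."""
        return (round(self.baseline_s * self.fs),
                round(self.execution_s * self.fs),
                round(self.imagery_s * self.fs))


# ---------------------------------------------------------------------------
# topographies
# ---------------------------------------------------------------------------

# Left-side corner imagery: contralateral (right-hemisphere) peak at FC6,
# then F4, then AF4; modest ipsilateral involvement.
_LL_WEIGHTS = {
    "AF3": 0.15, "AF4": 0.50, "F3": 0.20, "F4": 0.70, "F7": 0.10,
    "F8": 0.35, "FC5": 0.30, "FC6": 1.00, "T7": 0.05, "T8": 0.25,
    "P7": 0.05, "P8": 0.10, "O1": 0.05, "O2": 0.05,
}
# Bilateral vertical tasks over FC5/FC6/F3/F4; the lower-lip base map is
# broader (temporal/parietal involvement) than the upper-lip map.
_LU_WEIGHTS = {
    "AF3": 0.45, "AF4": 0.45, "F3": 0.70, "F4": 0.70, "F7": 0.25,
    "F8": 0.25, "FC5": 1.00, "FC6": 1.00, "T7": 0.20, "T8": 0.20,
    "P7": 0.10, "P8": 0.10, "O1": 0.05, "O2": 0.05,
}
_LD_WEIGHTS = {
    "AF3": 0.60, "AF4": 0.60, "F3": 0.80, "F4": 0.80, "F7": 0.45,
    "F8": 0.45, "FC5": 1.00, "FC6": 1.00, "T7": 0.40, "T8": 0.40,
    "P7": 0.25, "P8": 0.25, "O1": 0.15, "O2": 0.15,
}
# Cheek-bulge imagery engages the same sites as corner imagery but more
# strongly (element-wise >= after clipping at 1).
_CHEEK_SCALE = 1.15


def _mirror(weights: dict[str, float]) -> dict[str, float]:
    out = dict(weights)
    for left, right in MIRROR_PAIRS:
        out[left], out[right] = weights[right], weights[left]
    return out


def _as_vector(weights: dict[str, float],
               channels: ChannelSet) -> np.ndarray:
    return np.array([weights[lbl] for lbl in channels.labels])


def command_topography(command: str,
                       config: SimulationConfig | None = None
                       ) -> TopographyTemplate:
    """ERD weight template for one imagined tongue action."""
    config = config or SimulationConfig()
    montage = standard_montage()
    if command == "LL":
        w = _as_vector(_LL_WEIGHTS, montage)
    elif command == "LR":
        w = _as_vector(_mirror(_LL_WEIGHTS), montage)
    elif command == "CL":
        w = np.minimum(1.0, _CHEEK_SCALE * _as_vector(_LL_WEIGHTS, montage))
    elif command == "CR":
        w = np.minimum(1.0, _CHEEK_SCALE
                       * _as_vector(_mirror(_LL_WEIGHTS), montage))
    elif command == "LU":
        w = _as_vector(_LU_WEIGHTS, montage)
    elif command == "LD":
        ov = float(config.lu_ld_overlap)
        if not 0.0 <= ov <= 1.0:
            raise ValueError("lu_ld_overlap must be in [0, 1]")
        w = ((1.0 - ov) * _as_vector(_LD_WEIGHTS, montage)
             + ov * _as_vector(_LU_WEIGHTS, montage))
    else:
        raise ValueError(
            f"unknown command {command!r}; expected one of {COMMANDS}")
    return TopographyTemplate(command=command, weights=w)


# ---------------------------------------------------------------------------
# subject profiles
# ---------------------------------------------------------------------------

def _subject_entropy(subject_id: str, seed: int) -> list[int]:
    return [int(seed) & 0x7FFFFFFF, zlib.crc32(subject_id.encode())]


def make_subject_profile(config: SimulationConfig, subject_id: str,
                         seed: int) -> SubjectProfile:
    """Draw one subject's amplitudes/effect sizes; deterministic in
    ``(seed, subject_id)``."""
    ss = np.random.SeedSequence(_subject_entropy(subject_id, seed))
    rng = np.random.default_rng(ss)
    montage = standard_montage()
    occ = np.array([lbl in ("O1", "O2") for lbl in montage.labels])

    def lognorm(mean: float, cv: float, size=None):
        if mean <= 0 or cv <= 0:
            return mean if size is None else np.full(size, float(mean))
        sigma = np.sqrt(np.log1p(cv ** 2))
        mu = np.log(mean) - sigma ** 2 / 2
        return np.exp(rng.normal(mu, sigma, size=size))

    alpha = lognorm(config.alpha_amplitude_mean,
                    config.alpha_amplitude_cv, size=14)
    alpha = np.where(occ, config.occipital_alpha_gain * alpha, alpha)
    gain = 1.0 if config.effect_gain_sd <= 0 else max(
        0.0, float(rng.normal(1.0, config.effect_gain_sd)))
    jitter = np.maximum(
        0.0, 1.0 + config.topography_jitter_sd * rng.standard_normal(14))
    return SubjectProfile(
        subject_id=subject_id,
        alpha_amplitude=np.asarray(alpha, dtype=np.float64),
        background_scale=float(lognorm(config.background_scale_mean,
                                       config.background_scale_cv)),
        line_amplitude=float(lognorm(config.line_amplitude_mean,
                                     config.line_amplitude_cv)),
        effect_gain=gain,
        topography_jitter=jitter,
        rng_seed=int(ss.generate_state(1)[0] & 0x7FFFFFFF),
    )


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _one_over_f(rng: np.random.Generator, n_ch: int, n: int,
                exponent: float, fs: float) -> np.ndarray:
    """Unit-variance spectrally shaped (1/f^exponent power) noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _alpha_process(rng: np.random.Generator, n_ch: int, n: int,
                   band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance narrowband stochastic oscillator.

    White noise is band-limited with a zero-phase Butterworth filter;
    a 4 s synthesis margin on both sides is cropped away so the kept
    segment is stationary (the narrow band rings far longer than the
    filter's default edge handling assumes).
    """
    margin = int(4 * fs)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(
        sos, rng.standard_normal((n_ch, n + 2 * margin)), axis=1)
    x = x[:, margin:margin + n]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_trial(profile: SubjectProfile, command: str,
                   config: SimulationConfig | None = None,
                   seed: int | np.random.SeedSequence |
                   np.random.Generator = 0,
                   *, session_id: str = "S1",
                   trial_index: int = -1) -> RawRecording:
    """Generate one 15 s trial recording with phase-onset events.

    Alpha power during execution and imagery drops by the fraction
    ``w_i * g * E / 100`` relative to baseline (clipped at 1 with a
    logged warning if the jittered product exceeds full suppression).
    """
    config = config or SimulationConfig()
    if command not in COMMANDS:
        raise ValueError(
            f"unknown command {command!r}; expected one of {COMMANDS}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    montage = standard_montage()
    n_b, n_e, n_i = config.trial_samples
    n = n_b + n_e + n_i

    template = command_topography(command, config)
    w_eff = np.clip(template.weights * profile.topography_jitter, 0.0, 1.0)
    erd_fraction = (w_eff * profile.effect_gain
                    * config.nominal_erd_percent[command] / 100.0)
    if np.any(erd_fraction > 1.0):
        logger.warning(
            "trial %s/%s: ERD fraction exceeded 1 on %d channel(s); clipped",
            profile.subject_id, command, int(np.sum(erd_fraction > 1.0)))
        erd_fraction = np.minimum(erd_fraction, 1.0)

    background = (_one_over_f(rng, 14, n, config.background_exponent,
                              config.fs) * profile.background_scale)
    alpha = (_alpha_process(rng, 14, n, config.alpha_band, config.fs)
             * profile.alpha_amplitude[:, None])
    envelope = np.ones((14, n))
    envelope[:, n_b:] = np.sqrt(1.0 - erd_fraction)[:, None]
    alpha *= envelope

    t = np.arange(n) / config.fs
    phase = rng.uniform(0, 2 * np.pi)
    line = profile.line_amplitude * np.sin(
        2 * np.pi * config.line_freq * t + phase)
    noise = config.sensor_noise_uv * rng.standard_normal((14, n))

    data = background + alpha + line[None, :] + noise
    events = [(0, "baseline"), (n_b, "execution"), (n_b + n_e, "imagery")]
    return RawRecording(
        data=data, fs=config.fs, channels=montage, events=events,
        subject_id=profile.subject_id, session_id=session_id,
        pattern_id=command_pattern(command), trial_index=trial_index,
        command=command,
    )


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

def subject_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_subjects)]


def simulate_subject(config: SimulationConfig, subject_id: str,
                     seed: int) -> Iterator[RawRecording]:
    """Yield one subject's trials (3 patterns x 2 sessions x 24 trials),
    command order randomized per session with a seeded permutation."""
    profile = make_subject_profile(config, subject_id, seed)
    ss = np.random.SeedSequence(_subject_entropy(subject_id, seed) + [1])
    n_sessions = len(PATTERNS) * config.sessions_per_pattern
    n_trials = config.trials_per_subject
    children = ss.spawn(n_sessions + n_trials)
    order_rngs = [np.random.default_rng(c) for c in children[:n_sessions]]
    trial_seeds = children[n_sessions:]

    trial_index = 0
    session_no = 0
    for pattern_id, commands in PATTERNS.items():
        for sess in range(config.sessions_per_pattern):
            seq = np.array(
                list(commands) * config.trials_per_command_per_session)
            seq = order_rngs[session_no].permutation(seq)
            session_no += 1
            for cmd in seq:
                yield simulate_trial(
                    profile, str(cmd), config, trial_seeds[trial_index],
                    session_id=f"{pattern_id}-sess{sess + 1}",
                    trial_index=trial_index)
                trial_index += 1


def simulate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> list[RawRecording]:
    """Generate the full study (2160 trial recordings at defaults).

    Reproducible end-to-end: the same ``(config, seed)`` yields
    bit-identical signal matrices.
    """
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    recordings: list[RawRecording] = []
    for sid in subject_ids(config):
        recordings.extend(simulate_subject(config, sid, seed))
    return recordings
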