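"""Synthetic inertial recordings and cohorts for pipeline validation.

No patient recordings ship with this package, so every pipeline stage is
exercised against a generative model with the statistical structure the
scoring method assumes:

* a 1/f^beta fractal background per channel (postural sway, sensor drift);
* a rhythmic tremor component — a sinusoid with slow Brownian frequency
  jitter and slow sinusoidal amplitude modulation — whose RMS amplitude is
  expressed *relative to the unit-RMS background* (``rel_amp``), projected
  coherently onto all six axes through fixed per-subject direction cosines;
* additive wideband sensor noise whose gain distinguishes a high-SNR
  finger-mounted IMU from a lower-SNR smartphone; the two sensors of a
  subject observe the *same* background and tremor and differ only in
  their gains and noise realizations, emulating paired measurement;
* cohorts of essential-tremor (ET), Parkinson (PD) and control subjects,
  with tremor frequency drawn from group-specific distributions (ET ~6 Hz
  in 5-8 Hz, PD ~6.3 Hz in 4-7 Hz), group-specific amplitude ranges, and
  a clinical-severity surrogate rank-linked to tremor amplitude.  Controls
  carry a weak 8-12 Hz physiological oscillation partially outside the
  3.5-10 Hz scoring band, so classification is nontrivial.

Everything is a pure function of its seed(s): the same seed always yields
the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import ANGULAR_CHANNELS, CHANNELS, LINEAR_CHANNELS, Recording

__all__ = [
    "SubjectParams",
    "SensorModel",
    "FINGER_SENSOR",
    "PHONE_SENSOR",
    "CohortConfig",
    "Cohort",
    "fractal_noise",
    "tremor_component",
    "simulate_recording",
    "simulate_cohort",
]

GROUPS = ("ET", "PD", "CTRL")

#: amplitude-modulation frequency in Hz — slow waxing/waning of postural
#: tremor amplitude over tens of seconds
AM_FREQ_HZ = 0.1


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated subject."""

    group: str = "CTRL"
    tremor_freq: float = 10.0
    tremor_rel_amp: float = 0.0
    freq_jitter_sd: float = 0.2
    am_depth: float = 0.3
    beta: float = 1.0
    severity: float = 0.0
    seed: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        if self.tremor_rel_amp < 0:
            raise ParameterError("tremor_rel_amp must be nonnegative")
        if not 0 <= self.am_depth <= 1:
            raise ParameterError("am_depth must lie in [0, 1]")


@dataclass(frozen=True)
class SensorModel:
    """Gain model of one sensor type.

    The finger-mounted IMU has a higher oscillation-to-noise gain ratio
    than the smartphone; the spectra it records share the tremor's shape
    but sit on a lower wideband noise floor.
    """

    kind: str
    osc_gain: float
    noise_gain: float

    def __post_init__(self) -> None:
        if self.kind not in ("finger", "phone"):
            raise ParameterError("sensor kind must be 'finger' or 'phone'")
        if self.osc_gain <= 0 or self.noise_gain < 0:
            raise ParameterError("gains must be positive")


FINGER_SENSOR = SensorModel(kind="finger", osc_gain=1.0, noise_gain=0.2)
PHONE_SENSOR = SensorModel(kind="phone", osc_gain=0.9, noise_gain=0.6)

_SENSOR_CODE = {"finger": 0, "phone": 1}
_POSITION_CODE = {"P1": 0, "P2": 1, "unknown": 2}


def fractal_noise(n: int, rate: float, beta: float, seed) -> np.ndarray:
    """Zero-mean, unit-RMS noise with expected PSD proportional to 1/f^beta.

    White Gaussian noise is shaped in the frequency domain by f^(-beta/2)
    (DC removed) and transformed back; beta=0 gives white noise, beta=2 a
    random-walk-like spectrum.
    """
    if n < 2:
        raise ParameterError("need at least two samples")
    if not 0 <= beta <= 2:
        raise ParameterError("beta must lie in [0, 2]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def tremor_component(
    n: int,
    rate: float,
    f0: float,
    rel_amp: float,
    freq_jitter_sd: float = 0.0,
    am_depth: float = 0.0,
    seed=0,
) -> np.ndarray:
    """Rhythmic tremor waveform with RMS ``rel_amp`` (background units).

    The instantaneous frequency is ``f0`` plus a Brownian excursion scaled
    so its standard deviation reaches ``freq_jitter_sd`` Hz at the end of
    the record; the amplitude envelope is ``1 + am_depth*sin(2*pi*0.1 Hz*t
    + phase)``.  With zero jitter and zero modulation the output is a pure
    sinusoid at f0.
    """
    if not 0 < f0 < rate / 2:
        raise ParameterError("f0 must lie in (0, Nyquist)")
    if rel_amp < 0:
        raise ParameterError("rel_amp must be nonnegative")
    if rel_amp == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    f_inst = np.full(n, float(f0))
    if freq_jitter_sd > 0:
        brownian = np.cumsum(rng.standard_normal(n)) / np.sqrt(n)
        f_inst = f_inst + freq_jitter_sd * brownian
    phase = 2 * np.pi * (np.cumsum(f_inst) / rate + rng.random())
    envelope = 1.0
    if am_depth > 0:
        envelope = 1.0 + am_depth * np.sin(
            2 * np.pi * AM_FREQ_HZ * t + 2 * np.pi * rng.random()
        )
    x = envelope * np.sin(phase)
    rms = np.sqrt(np.mean(x**2))
    return rel_amp * x / rms


def _direction_cosines(rng: np.random.Generator) -> np.ndarray:
    """Unit 3-vector with every component bounded away from zero."""
    mags = 0.35 + 0.65 * rng.random(3)
    signs = np.where(rng.random(3) < 0.5, -1.0, 1.0)
    v = mags * signs
    return v / np.linalg.norm(v)


def simulate_recording(
    params: SubjectParams,
    sensor: SensorModel = PHONE_SENSOR,
    duration: float = 60.0,
    rate: float = 100.0,
    position: str = "unknown",
) -> Recording:
    """Six-channel recording: background + projected tremor + sensor noise.

    The per-channel signal is

        fractal background  +  osc_gain * c_i * tremor  +  noise_gain * white

    with direction cosines c_i fixed per subject (linear and angular
    triplets drawn separately, all components nonzero).  The background
    and tremor streams depend only on (params.seed, position), so paired
    finger/phone recordings of one subject observe identical motion and
    differ only in gains and sensor noise.
    """
    if duration < 16.0:
        raise ParameterError("duration must be at least 16 s (two windows)")
    n = round(duration * rate)
    pos_code = _POSITION_CODE[position]
    rng_subject = np.random.default_rng([params.seed, pos_code, 1])
    cos_lin = _direction_cosines(rng_subject)
    cos_ang = _direction_cosines(rng_subject)
    cosines = dict(zip(LINEAR_CHANNELS, cos_lin)) | dict(
        zip(ANGULAR_CHANNELS, cos_ang)
    )
    tremor = tremor_component(
        n,
        rate,
        params.tremor_freq,
        params.tremor_rel_amp,
        params.freq_jitter_sd,
        params.am_depth,
        seed=[params.seed, pos_code, 2],
    )
    sensor_code = _SENSOR_CODE[sensor.kind]
    channels = {}
    for i, name in enumerate(CHANNELS):
        background = fractal_noise(n, rate, params.beta, [params.seed, pos_code, 3, i])
        white = np.random.default_rng(
            [params.seed, pos_code, 4, sensor_code, i]
        ).standard_normal(n)
        channels[name] = (
            background
            + sensor.osc_gain * cosines[name] * tremor
            + sensor.noise_gain * white
        )
    return Recording(
        channels=channels,
        rate=rate,
        sensor=sensor.kind,
        position=position,
        subject_id=params.subject_id,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Group-level parameter distributions for cohort simulation.

    Frequencies are drawn from truncated normals anchored at the typical
    postural-tremor peaks (ET 6.0 +- 1.0 Hz within 5-8 Hz; PD 6.3 +- 1.3 Hz
    within 4-7 Hz; controls 8-12 Hz physiological).  Relative amplitudes
    are uniform in group-specific ranges; ET tremor is markedly larger than
    PD postural tremor, and controls stay at or below 0.3.
    """

    et_freq: tuple[float, float, float, float] = (6.0, 1.0, 5.0, 8.0)  # mu, sd, lo, hi
    pd_freq: tuple[float, float, float, float] = (6.3, 1.3, 4.0, 7.0)
    ctrl_freq: tuple[float, float, float, float] = (10.0, 1.0, 8.0, 12.0)
    et_rel_amp: tuple[float, float] = (2.0, 5.0)
    pd_rel_amp: tuple[float, float] = (0.5, 2.0)
    ctrl_rel_amp: tuple[float, float] = (0.1, 0.3)
    freq_jitter_sd: float = 0.2
    am_depth: tuple[float, float] = (0.1, 0.5)
    beta: tuple[float, float] = (0.8, 1.2)
    severity_noise: float = 0.25
    duration: float = 60.0
    rate: float = 100.0
    positions: tuple[str, ...] = ("P1", "P2")
    sensors: tuple[SensorModel, ...] = (FINGER_SENSOR, PHONE_SENSOR)


def _truncated_normal(rng, mu, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mu, lo, hi))


def _draw_subject(
    rng: np.random.Generator, group: str, config: CohortConfig, subject_id: str
) -> SubjectParams:
    freq_spec = {"ET": config.et_freq, "PD": config.pd_freq, "CTRL": config.ctrl_freq}[group]
    amp_lo, amp_hi = {
        "ET": config.et_rel_amp,
        "PD": config.pd_rel_amp,
        "CTRL": config.ctrl_rel_amp,
    }[group]
    rel_amp = float(rng.uniform(amp_lo, amp_hi))
    # severity surrogate: monotone in amplitude with bounded rater noise
    severity = rel_amp + float(rng.uniform(-config.severity_noise, config.severity_noise))
    severity = max(severity, 0.0)
    return SubjectParams(
        group=group,
        tremor_freq=_truncated_normal(rng, *freq_spec),
        tremor_rel_amp=rel_amp,
        freq_jitter_sd=config.freq_jitter_sd,
        am_depth=float(rng.uniform(*config.am_depth)),
        beta=float(rng.uniform(*config.beta)),
        severity=severity,
        seed=int(rng.integers(2**31)),
        subject_id=subject_id,
    )


@dataclass
class Cohort:
    """A simulated cohort: per-subject parameters and all recordings.

    Recordings are keyed by (subject_id, sensor kind, position).
    """

    subjects: list[SubjectParams]
    recordings: dict[tuple[str, str, str], Recording]
    config: CohortConfig = field(default_factory=CohortConfig)

    def table(self) -> pd.DataFrame:
        """Per-subject rows (subject_id, group, severity) without scores."""
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "severity": s.severity,
                }
                for s in self.subjects
            ]
        )


def simulate_cohort(
    n_et: int,
    n_pd: int,
    n_ctrl: int,
    config: CohortConfig | None = None,
    master_seed: int = 0,
) -> Cohort:
    """Draw a cohort and simulate every (sensor, position) recording.

    Fully deterministic given ``master_seed``: subject parameters, seeds
    and all sample streams derive from it.
    """
    if min(n_et, n_pd, n_ctrl) < 0:
        raise ParameterError("cohort counts must be nonnegative")
    config = config or CohortConfig()
    subjects: list[SubjectParams] = []
    counts = (("ET", n_et), ("PD", n_pd), ("CTRL", n_ctrl))
    j = 0
    for group, count in counts:
        for i in range(count):
            rng = np.random.default_rng([master_seed, j])
            subjects.append(_draw_subject(rng, group, config, f"{group}{i + 1:02d}"))
            j += 1
    recordings = {}
    for params in subjects:
        for sensor in config.sensors:
            for position in config.positions:
                recordings[(params.subject_id, sensor.kind, position)] = (
                    simulate_recording(
                        params,
                        sensor,
                        duration=config.duration,
                        rate=config.rate,
                        position=position,
                    )
                )
    return Cohort(subjects=subjects, recordings=recordings, config=config)
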