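"""Synthetic cohort generator for elbow sEMG muscle-tone recordings.

Emulates a two-channel (biceps/triceps brachii) surface-EMG acquisition with an
elbow electrogoniometer: per subject a 10 s rest recording, three 5 s maximum
voluntary contraction (MVC) trials per muscle, and one movement trial of 15
full elbow flexion--extension repetitions performed at a comfortable pace.

The four tone classes differ in the *activation envelope* driving each muscle:

* ``normal``    -- reciprocal activation: agonist active in its half-cycle,
                   antagonist nearly silent.
* ``spastic``   -- normal pattern plus a stretch-phase burst whose gain grows
                   with the angular speed of the stretch (velocity-dependent
                   hypertonia).
* ``rigid``     -- velocity-independent co-contraction: an elevated, constant
                   baseline in both muscles throughout the cycle (plastic
                   hypertonia).
* ``hypotonic`` -- the normal pattern scaled by an amplitude factor below 0.5.

The sEMG itself is amplitude-modulated band-limited Gaussian noise (20--450 Hz
carrier) with configurable contaminants: 60 Hz powerline, sub-5 Hz baseline
drift and broadband measurement noise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal as sps


class ToneClass(str, enum.Enum):
    """The four admissible muscle-tone classes."""

    SPASTIC = "spastic"
    RIGID = "rigid"
    HYPOTONIC = "hypotonic"
    NORMAL = "normal"


MUSCLES = ("biceps", "triceps")

#: Default cohort composition: subjects per tone class.
DEFAULT_CLASS_COUNTS = {
    ToneClass.SPASTIC: 10,
    ToneClass.RIGID: 10,
    ToneClass.HYPOTONIC: 9,
    ToneClass.NORMAL: 10,
}


class ClassParams(BaseModel):
    """Per-class envelope parameters (all activations on a 0--1 MVC scale)."""

    rest_level: float = 0.05          # antagonist / resting activation
    agonist_amp: float = 0.55         # peak reciprocal (agonist) activation
    spastic_burst_gain: float = 0.45  # burst amplitude at the reference speed
    spastic_velocity_ref: float = 150.0  # deg/s speed giving unit burst scale
    rigid_biceps_level: float = 0.50  # constant co-contraction levels
    rigid_triceps_level: float = 0.45
    hypotonic_factor: float = 0.35    # must stay < 0.5 (amplitude reduction)


class NoiseParams(BaseModel):
    """Contaminant levels, relative to the maximum-activation carrier RMS."""

    powerline_rel: float = 10 ** (-10 / 20)  # -10 dB 60 Hz sinusoid
    white_rel: float = 10 ** (-20 / 20)      # -20 dB broadband noise
    drift_rel: float = 0.10                  # <5 Hz baseline wander
    angle_noise_deg: float = 0.5             # goniometer noise (degrees)


class GeneratorConfig(BaseModel):
    """Acquisition-protocol and cohort parameters for the generator."""

    sampling_rate: float = 2000.0
    n_repetitions: int = 15
    rest_duration: float = 10.0
    mvc_duration: float = 5.0
    mvc_trials: int = 3
    cycle_duration: float = 2.0        # s per flexion-extension repetition
    cycle_jitter: float = 0.20         # +/- fractional jitter on durations
    angle_flexion: float = 140.0       # deg, full flexion
    angle_extension: float = 5.0       # deg, full extension
    carrier_band: tuple[float, float] = (20.0, 450.0)
    base_amplitude: float = 1.0        # mV at full (MVC) activation
    subject_gain_sd: float = 0.3       # log-sd of per-subject gain
    param_jitter_sd: float = 0.10      # log-sd of per-subject envelope params
    class_counts: dict[ToneClass, int] = Field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    class_params: ClassParams = Field(default_factory=ClassParams)
    noise: NoiseParams = Field(default_factory=NoiseParams)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.sampling_rate <= 2 * 500.0:
            raise ValueError("sampling_rate must exceed 1000 Hz (2x500 Hz)")
        if self.n_repetitions < 0:
            raise ValueError("n_repetitions must be >= 0")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if not 0 < self.class_params.hypotonic_factor < 0.5:
            raise ValueError("hypotonic_factor must lie in (0, 0.5)")
        return self


@dataclass
class RecordingSession:
    """One subject's recordings: rest, MVC trials and the movement trial.

    Channel order is (biceps, triceps) everywhere.  ``movement`` carries the
    two sEMG channels plus the elbow angle in degrees (0 deg = full extension,
    ~140 deg = full flexion).
    """

    subject_id: str
    tone_class: ToneClass
    sampling_rate: float
    rest: np.ndarray                      # (n, 2)
    mvc: dict[str, list[np.ndarray]]      # muscle -> list of 1-D trials
    movement_emg: np.ndarray              # (n, 2)
    movement_angle: np.ndarray            # (n,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.movement_angle.size:
            lo, hi = self.movement_angle.min(), self.movement_angle.max()
            if lo < -1e-9 or hi > 150.0 + 1e-9:
                raise ValueError("movement angle must stay within [0, 150] deg")


class EmptyProtocolError(ValueError):
    """Raised when a protocol with zero repetitions is requested."""


# ---------------------------------------------------------------------------
# angle trace
# ---------------------------------------------------------------------------

def make_angle_trace(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic elbow-angle trace with ``n_repetitions`` cycles.

    Each cycle starts and ends at full flexion, dips to full extension at its
    midpoint (raised-cosine profile) and has its duration jittered uniformly
    by ``+/- cycle_jitter``.  Returns ``(angle_deg, phase)`` where ``phase``
    is the noiseless normalized cycle position in [0, 1) (restarting each
    cycle); the trace's final sample closes the last cycle at full flexion.
    """
    if config.n_repetitions < 1:
        raise EmptyProtocolError("movement protocol requires >= 1 repetition")
    fs = config.sampling_rate
    durations = config.cycle_duration * (
        1.0 + config.cycle_jitter * rng.uniform(-1.0, 1.0, config.n_repetitions)
    )
    phases = []
    for dur in durations:
        n = max(int(round(dur * fs)), 8)
        phases.append(np.arange(n) / n)
    phase = np.concatenate(phases + [np.zeros(1)])  # closing flexion sample
    flex, ext = config.angle_flexion, config.angle_extension
    angle = ext + (flex - ext) * 0.5 * (1.0 + np.cos(2 * np.pi * phase))
    if config.noise.angle_noise_deg > 0:
        angle = angle + rng.normal(0.0, config.noise.angle_noise_deg, angle.size)
        angle = np.clip(angle, 0.0, 150.0)
    return angle, phase


def angular_velocity(angle: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Angular velocity in deg/s by central differences."""
    return np.gradient(angle) * sampling_rate


# ---------------------------------------------------------------------------
# activation envelopes
# ---------------------------------------------------------------------------

def activation_envelope(
    tone_class: ToneClass,
    muscle: str,
    phase: np.ndarray | float,
    angular_velocity: np.ndarray | float,
    params: ClassParams | None = None,
) -> np.ndarray:
    """Muscle activation level in [0, 1] for a given cycle phase and speed.

    Phase convention: the cycle runs flexion -> extension -> flexion, so the
    elbow extends (biceps lengthens) on phase in (0, 0.5) and flexes (triceps
    lengthens) on (0.5, 1).  The agonist bumps are half-sine lobes; the
    spastic stretch burst is applied to whichever muscle is being lengthened
    and scales linearly with angular speed up to saturation.
    """
    params = params or ClassParams()
    if muscle not in MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}")
    p = np.asarray(phase, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("phase must lie in [0, 1]")
    v = np.abs(np.asarray(angular_velocity, dtype=float))

    # reciprocal (normal) pattern: triceps agonist on (0, .5), biceps on (.5, 1)
    if muscle == "biceps":
        lobe = np.maximum(0.0, np.sin(2 * np.pi * (p - 0.5)))
        stretch = np.maximum(0.0, np.sin(2 * np.pi * p))  # lengthening lobe
    else:
        lobe = np.maximum(0.0, np.sin(2 * np.pi * p))
        stretch = np.maximum(0.0, np.sin(2 * np.pi * (p - 0.5)))
    normal = params.rest_level + params.agonist_amp * lobe

    if tone_class is ToneClass.NORMAL:
        env = normal
    elif tone_class is ToneClass.HYPOTONIC:
        env = params.hypotonic_factor * normal
    elif tone_class is ToneClass.RIGID:
        level = (
            params.rigid_biceps_level
            if muscle == "biceps"
            else params.rigid_triceps_level
        )
        env = np.full_like(p, level)
    elif tone_class is ToneClass.SPASTIC:
        burst = params.spastic_burst_gain * np.minimum(
            v / params.spastic_velocity_ref, 2.0
        )
        env = normal + burst * stretch
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown tone class {tone_class!r}")
    return np.clip(env, 0.0, 1.0)


# ---------------------------------------------------------------------------
# sEMG synthesis
# ---------------------------------------------------------------------------

def _bandlimited_carrier(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (the sEMG carrier)."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / rms if rms > 0 else carrier


def synthesize_emg(
    envelope: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    contaminants: bool = True,
    gain: float = 1.0,
) -> np.ndarray:
    """One sEMG channel: envelope-modulated carrier plus contaminants.

    The carrier is zero-mean band-limited (default 20--450 Hz) Gaussian noise
    at unit RMS, multiplied by the activation envelope and ``base_amplitude``.
    With ``contaminants`` on, a 60 Hz powerline sinusoid, a sub-5 Hz baseline
    drift and white measurement noise are added at the configured levels
    (relative to the full-activation carrier RMS).
    """
    n = envelope.size
    fs = config.sampling_rate
    amp = config.base_amplitude * gain
    if n == 0:
        return np.zeros(0)
    carrier = _bandlimited_carrier(n, fs, config.carrier_band, rng)
    emg = amp * envelope * carrier
    if contaminants:
        nz = config.noise
        t = np.arange(n) / fs
        phase0 = rng.uniform(0, 2 * np.pi)
        emg = emg + amp * nz.powerline_rel * np.sin(2 * np.pi * 60.0 * t + phase0)
        if nz.drift_rel > 0:
            slow = rng.standard_normal(n)
            sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
            slow = sps.sosfiltfilt(sos, slow)
            peak = np.max(np.abs(slow))
            if peak > 0:
                emg = emg + amp * nz.drift_rel * slow / peak
        emg = emg + amp * nz.white_rel * rng.standard_normal(n)
    return emg


def _mvc_envelope(config: GeneratorConfig) -> np.ndarray:
    """Full-activation envelope for an MVC trial (0.25 s raised-cosine ramps)."""
    n = int(round(config.mvc_duration * config.sampling_rate))
    env = np.ones(n)
    ramp = int(round(0.25 * config.sampling_rate))
    if 0 < ramp < n // 2:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def _jitter_params(
    params: ClassParams, rng: np.random.Generator, sd: float
) -> ClassParams:
    """Lognormal per-subject jitter on the envelope amplitudes."""
    upd = {}
    for name in (
        "rest_level",
        "agonist_amp",
        "spastic_burst_gain",
        "rigid_biceps_level",
        "rigid_triceps_level",
    ):
        upd[name] = getattr(params, name) * float(np.exp(rng.normal(0.0, sd)))
    hypo = params.hypotonic_factor * float(np.exp(rng.normal(0.0, sd)))
    upd["hypotonic_factor"] = min(hypo, 0.49)
    return params.model_copy(update=upd)


def generate_session(
    subject_id: str,
    tone_class: ToneClass,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> RecordingSession:
    """Synthesize one subject's full acquisition protocol."""
    fs = config.sampling_rate
    gain = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
    params = _jitter_params(config.class_params, rng, config.param_jitter_sd)

    n_rest = int(round(config.rest_duration * fs))
    rest_env = np.full(n_rest, 0.02)
    rest = np.column_stack(
        [synthesize_emg(rest_env, config, rng, gain=gain) for _ in MUSCLES]
    )

    mvc_env = _mvc_envelope(config)
    mvc = {
        muscle: [
            synthesize_emg(mvc_env, config, rng, gain=gain)
            for _ in range(config.mvc_trials)
        ]
        for muscle in MUSCLES
    }

    angle, phase = make_angle_trace(config, rng)
    vel = angular_velocity(angle, fs)
    chans = []
    for muscle in MUSCLES:
        env = activation_envelope(tone_class, muscle, phase, vel, params)
        chans.append(synthesize_emg(env, config, rng, gain=gain))
    movement = np.column_stack(chans)

    return RecordingSession(
        subject_id=subject_id,
        tone_class=tone_class,
        sampling_rate=fs,
        rest=rest,
        mvc=mvc,
        movement_emg=movement,
        movement_angle=angle,
        meta={"gain": gain},
    )


_CLASS_PREFIX = {
    ToneClass.SPASTIC: "Sp",
    ToneClass.RIGID: "Ri",
    ToneClass.HYPOTONIC: "Hy",
    ToneClass.NORMAL: "No",
}


def generate_cohort(config: GeneratorConfig) -> list[RecordingSession]:
    """Generate the full cohort (default 10 spastic / 10 rigid / 9 hypotonic /
    10 normal subjects).  Deterministic: the same config (including seed)
    yields bit-identical sessions."""
    root = np.random.SeedSequence(config.seed)
    sessions: list[RecordingSession] = []
    order = [tc for tc in ToneClass if config.class_counts.get(tc, 0) > 0]
    seeds = root.spawn(sum(config.class_counts.get(tc, 0) for tc in order))
    k = 0
    for tc in order:
        for i in range(config.class_counts[tc]):
            rng = np.random.default_rng(seeds[k])
            k += 1
            sid = f"{_CLASS_PREFIX[tc]}{i + 1:02d}"
            sessions.append(generate_session(sid, tc, config, rng))
    return sessions


# ---------------------------------------------------------------------------
# on-disk dialect
# ---------------------------------------------------------------------------

def write_session(session: RecordingSession, out_dir: Path | str) -> Path:
    """Write one subject's directory of CSVs plus ``manifest.json``."""
    import pandas as pd

    out = Path(out_dir) / session.subject_id
    out.mkdir(parents=True, exist_ok=True)
    fs = session.sampling_rate

    def frame(emg: np.ndarray, angle: np.ndarray | None = None) -> pd.DataFrame:
        n = emg.shape[0]
        cols = {"time_s": np.arange(n) / fs}
        cols["biceps"] = emg[:, 0]
        cols["triceps"] = emg[:, 1]
        if angle is not None:
            cols["angle_deg"] = angle
        return pd.DataFrame(cols)

    frame(session.rest).to_csv(out / "rest.csv", index=False)
    for muscle in MUSCLES:
        for i, trial in enumerate(session.mvc[muscle], start=1):
            pd.DataFrame(
                {"time_s": np.arange(trial.size) / fs, muscle: trial}
            ).to_csv(out / f"mvc_{muscle}_{i}.csv", index=False)
    frame(session.movement_emg, session.movement_angle).to_csv(
        out / "movement.csv", index=False
    )
    manifest = {
        "subject_id": session.subject_id,
        "tone_class": session.tone_class.value,
        "sampling_rate": fs,
        "meta": session.meta,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_session(subject_dir: Path | str) -> RecordingSession:
    """Read a subject directory written by :func:`write_session`."""
    import pandas as pd

    d = Path(subject_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    fs = float(manifest["sampling_rate"])
    rest_df = pd.read_csv(d / "rest.csv")
    rest = rest_df[["biceps", "triceps"]].to_numpy()
    mvc: dict[str, list[np.ndarray]] = {m: [] for m in MUSCLES}
    for muscle in MUSCLES:
        i = 1
        while (d / f"mvc_{muscle}_{i}.csv").exists():
            mvc[muscle].append(
                pd.read_csv(d / f"mvc_{muscle}_{i}.csv")[muscle].to_numpy()
            )
            i += 1
    mov = pd.read_csv(d / "movement.csv")
    return RecordingSession(
        subject_id=manifest["subject_id"],
        tone_class=ToneClass(manifest["tone_class"]),
        sampling_rate=fs,
        rest=rest,
        mvc=mvc,
        movement_emg=mov[["biceps", "triceps"]].to_numpy(),
        movement_angle=mov["angle_deg"].to_numpy(),
        meta=manifest.get("meta", {}),
    )


def write_cohort(sessions: list[RecordingSession], out_dir: Path | str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_session(s, out)
    index = [
        {"subject_id": s.subject_id, "tone_class": s.tone_class.value}
        for s in sessions
    ]
    (out / "cohort.json").write_text(json.dumps(index, indent=2))
    return out


def read_cohort(cohort_dir: Path | str) -> list[RecordingSession]:
    d = Path(cohort_dir)
    index = json.loads((d / "cohort.json").read_text())
    return [read_session(d / entry["subject_id"]) for entry in index]
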