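"""Synthetic paired-device accelerometer benchmark.

The study protocols this package validates against were recorded with two
simultaneously worn devices — a consumer smartwatch (10 Hz, ±2 g) and a
research-grade monitor (100 Hz, ±8 g) — across three protocols: a
mechanical 1-D shaker, treadmill gait at six speeds, and 15 common daily
activities performed by 40 adults with indirect-calorimetry METs. The raw
recordings are not public, so this module generates a statistical
surrogate with the same separability structure:

* ground-truth body acceleration at a 100 Hz reference rate — periodic
  locomotion with its fundamental inside the 0.6–2.5 Hz band, near-static
  sedentary behaviour, and *complex* activities built by concatenating
  heterogeneous sub-action segments under one label;
* a static 1 g gravity component whose orientation is posture-dependent
  per activity (the inclination-angle features are meaningless without a
  gravitational reference);
* imperfect device recordings: axis misalignment, gain, anti-aliased
  decimation to the device rate, sensor noise, and range saturation.

Signals are statistical surrogates, not biomechanical simulations. All
randomness derives from a single seed through named substreams, so a
fixed configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .errors import ConfigError
from .labels import ActivityMeta, load_taxonomy, save_taxonomy
from .signal_io import AccelRecording, DeviceProfile, write_accel_csv

REFERENCE_RATE = 100.0  # Hz of ground-truth signals

#: Default paired device profiles. The smartwatch records at 10 Hz with a
#: narrow ±2 g range, a mild gain deficit (the amplitude shift such
#: consumer devices show) and a few degrees of strap misalignment; the
#: research monitor is treated as the reference frame.
DEFAULT_DEVICES = (
    DeviceProfile(
        name="smartwatch",
        sampling_rate=10.0,
        dynamic_range=2.0,
        gain=0.9,
        misalignment=(4.0, -3.0, 5.0),
        noise_sd=0.015,
    ),
    DeviceProfile(
        name="actigraph",
        sampling_rate=100.0,
        dynamic_range=8.0,
        gain=1.0,
        misalignment=None,
        noise_sd=0.005,
    ),
)

SHAKER_FREQUENCIES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)  # Hz
TREADMILL_SPEEDS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # mph


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SubAction:
    """One simple action inside a complex activity's pool."""

    frequency: float  # Hz; 0 for an aperiodic fidget/posture action
    amplitude: float  # g
    axis: str  # dominant axis: x, y or z
    duration_range: tuple[float, float]  # seconds


@dataclass(frozen=True)
class ActivitySignalModel:
    """Statistical signal model for one activity.

    ``kind`` is ``simple`` (one stationary process for the whole session)
    or ``complex`` (random concatenation of >= 3 pool sub-actions).
    ``axis_mix`` distributes the motion across device axes (unit vector);
    ``gravity_direction`` is the posture's static 1 g orientation.
    """

    activity_name: str
    kind: str  # simple | complex
    base_frequency: float  # Hz; 0 if aperiodic
    amplitude: float  # g
    axis_mix: tuple[float, float, float]
    gravity_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    noise_sd: float = 0.01  # g
    action_pool: tuple[SubAction, ...] = ()
    met_anchor: float | None = None  # nominal METs; None -> intensity-band midpoint

    def __post_init__(self):
        if self.kind not in ("simple", "complex"):
            raise ConfigError(f"kind must be simple|complex, got {self.kind!r}")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.base_frequency >= REFERENCE_RATE / 2:
            raise ConfigError("base_frequency must be below the reference Nyquist")
        if self.kind == "complex" and len(self.action_pool) < 3:
            raise ConfigError("complex activities need an action pool of >= 3 entries")
        if not np.isclose(np.linalg.norm(self.axis_mix), 1.0, atol=1e-6):
            raise ConfigError("axis_mix must be a unit vector")


@dataclass(frozen=True)
class ParticipantProfile:
    """Inter-person variation: overall movement amplitude and tempo scales."""

    participant_id: str
    amplitude_scale: float = 1.0
    tempo_scale: float = 1.0

    def __post_init__(self):
        if self.amplitude_scale <= 0 or self.tempo_scale <= 0:
            raise ConfigError("participant scales must be > 0")


def _mix(axis: str, dominance: float = 0.82) -> tuple[float, float, float]:
    base = {"x": [1.0, 0.0, 0.0], "y": [0.0, 1.0, 0.0], "z": [0.0, 0.0, 1.0]}[axis]
    v = np.full(3, np.sqrt((1 - dominance**2) / 2))
    v[np.argmax(base)] = dominance
    return tuple(_unit(v))


def _model(name, kind, f, amp, mix, gravity, noise, pool=(), met=None):
    return ActivitySignalModel(
        activity_name=name,
        kind=kind,
        base_frequency=f,
        amplitude=amp,
        axis_mix=tuple(_unit(mix)),
        gravity_direction=tuple(_unit(gravity)),
        noise_sd=noise,
        action_pool=tuple(SubAction(*e) for e in pool),
        met_anchor=met,
    )


_WALK_GRAVITY = (0.25, 0.88, 0.40)  # arm hanging, wrist-worn device
_WALK_MIX = (0.45, 0.78, 0.43)
_UPPER_GRAVITY = (0.88, 0.34, 0.33)
_TOTAL_GRAVITY = (0.58, 0.63, 0.51)

#: Default per-activity signal models. Amplitudes track the taxonomy's
#: intensity class (sedentary < light < moderate); walking fundamentals sit
#: inside the 0.6-2.5 Hz locomotion band; complex activities draw from
#: heterogeneous pools so one label covers several distinct actions.
DEFAULT_ACTIVITY_MODELS: dict[str, ActivitySignalModel] = {
    m.activity_name: m
    for m in [
        _model("Computer work", "simple", 0.0, 0.02, (0.62, 0.54, 0.57),
               (0.93, 0.26, 0.26), 0.008, met=1.3),
        _model("Ironing", "complex", 0.0, 0.12, _mix("x"), _UPPER_GRAVITY, 0.010,
               pool=[(0.9, 0.12, "x", (4, 10)), (1.4, 0.10, "y", (3, 8)),
                     (0.0, 0.05, "z", (3, 8)), (0.6, 0.08, "x", (4, 9))], met=1.9),
        _model("Yoga", "complex", 0.0, 0.08, _mix("y"), _TOTAL_GRAVITY, 0.008,
               pool=[(0.3, 0.08, "y", (6, 14)), (0.0, 0.04, "x", (6, 12)),
                     (0.5, 0.10, "z", (5, 12))], met=2.3),
        _model("Shopping", "complex", 0.0, 0.13, _mix("y"), (0.60, 0.62, 0.50), 0.012,
               pool=[(1.1, 0.14, "y", (5, 12)), (0.0, 0.06, "x", (4, 10)),
                     (0.7, 0.10, "z", (4, 10)), (1.6, 0.12, "y", (3, 8))], met=2.3),
        _model("Laundry", "complex", 0.0, 0.11, _mix("z"), (0.90, 0.30, 0.31), 0.010,
               pool=[(0.8, 0.13, "z", (4, 10)), (1.2, 0.11, "x", (3, 8)),
                     (0.0, 0.05, "y", (4, 9))], met=2.1),
        _model("Washing windows", "complex", 0.0, 0.32, _mix("y"), (0.86, 0.36, 0.36), 0.015,
               pool=[(1.8, 0.35, "y", (4, 10)), (1.3, 0.28, "x", (4, 9)),
                     (0.0, 0.10, "z", (3, 7)), (2.2, 0.30, "y", (3, 8))], met=3.2),
        _model("Home maintenance", "complex", 0.0, 0.30, _mix("z"), (0.84, 0.40, 0.37), 0.015,
               pool=[(1.0, 0.30, "z", (4, 10)), (2.0, 0.35, "x", (3, 8)),
                     (0.0, 0.12, "y", (4, 9)), (1.5, 0.25, "z", (3, 8))], met=3.3),
        _model("Replacing bed sheet", "complex", 0.0, 0.33, _mix("x"), (0.88, 0.32, 0.35), 0.015,
               pool=[(0.9, 0.32, "x", (4, 9)), (1.6, 0.38, "z", (3, 8)),
                     (0.0, 0.10, "y", (3, 7))], met=3.4),
        _model("Mopping", "complex", 0.0, 0.31, _mix("y"), (0.87, 0.37, 0.33), 0.015,
               pool=[(0.7, 0.30, "y", (5, 12)), (1.1, 0.33, "x", (4, 10)),
                     (1.9, 0.28, "z", (3, 8)), (0.0, 0.08, "y", (3, 6))], met=3.5),
        _model("Trash removal", "complex", 0.0, 0.34, _mix("y"), _TOTAL_GRAVITY, 0.018,
               pool=[(1.2, 0.38, "y", (4, 10)), (0.8, 0.30, "z", (4, 9)),
                     (0.0, 0.15, "x", (3, 7)), (1.7, 0.33, "x", (3, 8))], met=3.8),
        _model("Heavy lifting", "complex", 0.0, 0.40, _mix("x"), (0.62, 0.60, 0.50), 0.020,
               pool=[(0.5, 0.45, "x", (5, 12)), (0.9, 0.40, "z", (4, 9)),
                     (0.0, 0.20, "y", (3, 7))], met=4.5),
        _model("Leisure walk", "simple", 1.70, 0.30, _WALK_MIX, _WALK_GRAVITY, 0.010, met=3.3),
        _model("Rapid walk", "simple", 1.95, 0.50, _WALK_MIX, _WALK_GRAVITY, 0.010, met=4.3),
        _model("Walk at RPE 1", "simple", 1.50, 0.24, _WALK_MIX, _WALK_GRAVITY, 0.010, met=3.1),
        _model("Walk at RPE 5", "simple", 2.05, 0.55, _WALK_MIX, _WALK_GRAVITY, 0.010, met=4.8),
    ]
}

#: MET bands by intensity class (used for validation and as anchor fallback).
MET_BANDS = {"sedentary": (1.0, 1.5), "light": (1.6, 2.9), "moderate": (3.0, 6.0)}


@dataclass
class SyntheticConfig:
    """Full benchmark configuration; ``seed`` makes output bit-reproducible."""

    seed: int = 1
    n_participants: int = 40
    taxonomy: dict[str, ActivityMeta] = field(default_factory=load_taxonomy)
    models: dict[str, ActivitySignalModel] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_MODELS)
    )
    devices: tuple[DeviceProfile, DeviceProfile] = DEFAULT_DEVICES
    met_noise_sd: float = 0.3
    reference_rate: float = REFERENCE_RATE

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigError("need n_participants >= 2")
        if len(self.devices) != 2:
            raise ConfigError("exactly two device profiles required")
        missing = set(self.taxonomy) - set(self.models)
        if missing:
            raise ConfigError(f"activities without a signal model: {sorted(missing)}")


@dataclass
class Session:
    """One (participant, activity) recording session."""

    participant: ParticipantProfile
    meta: ActivityMeta
    truth: AccelRecording
    recordings: dict[str, AccelRecording]
    met: float

    @property
    def participant_id(self) -> str:
        return self.participant.participant_id

    @property
    def activity_name(self) -> str:
        return self.meta.name


@dataclass
class BenchmarkBundle:
    """All sessions of one synthetic study run plus the generating config."""

    sessions: list[Session]
    config: SyntheticConfig

    def manifest(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "participant": s.participant_id,
                    "activity": s.activity_name,
                    "met": s.met,
                    **{f"file_{d}": _session_filename(s, d) for d in s.recordings},
                }
                for s in self.sessions
            ]
        )

    def met_table(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            [
                {"participant": s.participant_id, "activity": s.activity_name, "met": s.met}
                for s in self.sessions
            ]
        )


def _rng(*key: int) -> np.random.Generator:
    """Named substream: deterministic, order-independent derivation."""
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _smooth_noise(rng, n: int, rate: float, cutoff: float = 2.0) -> np.ndarray:
    """Unit-SD low-passed Gaussian noise (aperiodic movement surrogate)."""
    w = rng.standard_normal(n)
    if n > 24:
        sos = sps.butter(4, cutoff, btype="low", fs=rate, output="sos")
        w = sps.sosfiltfilt(sos, w)
    sd = w.std()
    return w / sd if sd > 0 else w


def _periodic_wave(rng, n: int, rate: float, freq: float, harmonic: float = 0.10) -> np.ndarray:
    """Quasi-periodic unit-amplitude wave with a weak 2nd harmonic and a
    slow amplitude envelope (stride-to-stride variation)."""
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    phase2 = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * t + phase) + harmonic * np.sin(
        4 * np.pi * freq * t + phase2
    )
    env = 1.0 + 0.22 * _smooth_noise(rng, n, rate, cutoff=0.15)
    return wave * np.clip(env, 0.2, None)


def _gravity_vector(rng, direction, jitter_deg: float = 5.0) -> np.ndarray:
    """1 g static component: the posture direction plus a small random tilt."""
    tilt = np.deg2rad(rng.normal(0.0, jitter_deg, size=3))
    c, s = np.cos(tilt), np.sin(tilt)
    rx = np.array([[1, 0, 0], [0, c[0], -s[0]], [0, s[0], c[0]]])
    ry = np.array([[c[1], 0, s[1]], [0, 1, 0], [-s[1], 0, c[1]]])
    rz = np.array([[c[2], -s[2], 0], [s[2], c[2], 0], [0, 0, 1]])
    return rz @ ry @ rx @ _unit(direction)


def simulate_shaker(
    frequency: float,
    axis: str,
    duration: float,
    amplitude: float = 1.0,
    rate: float = REFERENCE_RATE,
) -> AccelRecording:
    """Ground-truth 1-D shaker-table signal: a pure sinusoid on one axis.

    The shaker drives a single axis; the other axes are identically zero
    (no gravity — the table moves in the horizontal plane).
    """
    if frequency <= 0 or duration <= 0:
        raise ValueError("frequency and duration must be > 0")
    if frequency >= rate / 2:
        raise ValueError(f"frequency {frequency} Hz >= Nyquist of {rate} Hz reference")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    samples = np.zeros((n, 3))
    samples[:, {"x": 0, "y": 1, "z": 2}[axis]] = amplitude * np.sin(2 * np.pi * frequency * t)
    return AccelRecording(device_id="truth", sampling_rate=rate, samples=samples)


def shaker_amplitude(frequency: float, peak: float = 1.0, top_frequency: float = 3.5) -> float:
    """Acceleration amplitude of a constant-displacement shaker at ``frequency``.

    A mechanical shaker oscillating with fixed displacement d produces
    acceleration amplitude (2πf)² d, so amplitude grows with the square of
    the speed setting; ``peak`` is the amplitude at the top speed.
    """
    return peak * (frequency / top_frequency) ** 2


def simulate_treadmill(
    speed_mph: float,
    duration: float,
    seed: int,
    rate: float = REFERENCE_RATE,
) -> AccelRecording:
    """Wrist-worn gait signal for one treadmill speed.

    Cadence-derived arm-swing frequency grows with belt speed
    (0.9 + 0.25·mph Hz, inside the locomotion band at walking speeds) and
    swing amplitude grows roughly linearly with speed.
    """
    rng = _rng(seed, 71)
    freq = 0.9 + 0.25 * speed_mph
    amp = 0.08 * speed_mph
    n = int(round(duration * rate))
    dyn = _segment(rng, n, rate, freq, amp, _unit(_WALK_MIX), noise_sd=0.01)
    gravity = _gravity_vector(rng, _WALK_GRAVITY)
    return AccelRecording(device_id="truth", sampling_rate=rate, samples=dyn + gravity)


def _segment(rng, n, rate, freq, amp, mix, noise_sd):
    if freq > 0:
        wave = _periodic_wave(rng, n, rate, freq)
    else:
        wave = _smooth_noise(rng, n, rate, cutoff=1.5)
    dyn = amp * np.outer(wave, mix)
    if noise_sd > 0:
        # body-motion jitter is low-frequency; wideband noise is a property
        # of the recording device, added in record_with_device
        jitter = np.column_stack(
            [_smooth_noise(rng, n, rate, cutoff=3.0) for _ in range(3)]
        )
        dyn += noise_sd * jitter
    return dyn


def simulate_activity(
    meta: ActivityMeta,
    model: ActivitySignalModel,
    participant: ParticipantProfile,
    seed: int,
    rate: float = REFERENCE_RATE,
) -> AccelRecording:
    """Ground-truth session signal for one (participant, activity).

    Simple activities emit one stationary process for the whole duration;
    complex activities concatenate randomly drawn sub-action segments
    (with per-segment posture jitter) until the duration is filled. The
    static 1 g gravity component is oriented by the activity's posture.
    Identical inputs yield bit-identical output.
    """
    if meta.duration <= 0:
        raise ValueError("duration must be > 0")
    if model.kind == "complex" and not model.action_pool:
        raise ConfigError(f"{meta.name}: complex activity with empty action pool")
    rng = _rng(seed, 11)
    n = int(round(meta.duration * 60 * rate))
    amp_scale = participant.amplitude_scale
    if model.kind == "simple":
        dyn = _segment(
            rng, n, rate,
            model.base_frequency * participant.tempo_scale,
            model.amplitude * amp_scale,
            _unit(model.axis_mix), model.noise_sd,
        )
        gravity = _gravity_vector(rng, model.gravity_direction)
        samples = dyn + gravity
    else:
        pieces = []
        filled = 0
        while filled < n:
            action = model.action_pool[rng.integers(len(model.action_pool))]
            dur = rng.uniform(*action.duration_range)
            seg_n = min(int(round(dur * rate)), n - filled)
            if seg_n <= 0:
                break
            seg = _segment(
                rng, seg_n, rate,
                action.frequency * participant.tempo_scale,
                action.amplitude * amp_scale,
                _unit(_mix(action.axis)), model.noise_sd,
            )
            # per-segment posture jitter: complex activities change stance
            seg += _gravity_vector(rng, model.gravity_direction)
            pieces.append(seg)
            filled += seg_n
        samples = np.concatenate(pieces, axis=0)
    return AccelRecording(device_id="truth", sampling_rate=rate, samples=samples)


def record_with_device(
    truth: AccelRecording, profile: DeviceProfile, seed: int
) -> AccelRecording:
    """Pass a ground-truth signal through an imperfect device.

    Applies, in order: axis misalignment rotation, gain, anti-aliased
    decimation to the device rate, additive Gaussian sensor noise, and
    symmetric range saturation at ±dynamic_range.
    """
    if profile.sampling_rate > truth.sampling_rate + 1e-9:
        raise ValueError("device rate cannot exceed the truth reference rate")
    samples = truth.samples @ profile.rotation.T
    samples = profile.gain * samples
    if profile.sampling_rate < truth.sampling_rate:
        factor = truth.sampling_rate / profile.sampling_rate
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("truth rate must be an integer multiple of the device rate")
        factor = int(round(factor))
        cutoff = 0.45 * profile.sampling_rate
        sos = sps.butter(8, cutoff, btype="low", fs=truth.sampling_rate, output="sos")
        samples = sps.sosfiltfilt(sos, samples, axis=0)[::factor]
    if profile.noise_sd > 0:
        rng = _rng(seed, 13)
        samples = samples + rng.normal(0.0, profile.noise_sd, samples.shape)
    samples = np.clip(samples, -profile.dynamic_range, profile.dynamic_range)
    return AccelRecording(
        device_id=profile.name,
        sampling_rate=profile.sampling_rate,
        samples=samples,
        start_time=truth.start_time,
        profile=profile,
    )


def simulate_mets(
    meta: ActivityMeta,
    participant: ParticipantProfile,
    met_noise_sd: float,
    seed: int,
    anchor: float | None = None,
) -> float:
    """Simulated calorimetry MET value for one session.

    The value is drawn around a nominal per-activity anchor inside the
    intensity class's band (sedentary [1.0, 1.5], light [1.6, 2.9],
    moderate [3.0, 6.0]), scaled by the participant's tempo and perturbed
    with Gaussian measurement noise; always > 0.
    """
    lo, hi = MET_BANDS[meta.intensity]
    if anchor is None:
        anchor = 0.5 * (lo + hi)
    if not lo <= anchor <= hi:
        raise ConfigError(
            f"{meta.name}: MET anchor {anchor} outside the {meta.intensity} band [{lo}, {hi}]"
        )
    rng = _rng(seed, 17)
    value = anchor * participant.tempo_scale + rng.normal(0.0, met_noise_sd)
    return float(max(value, 0.05))


def _activity_counts(config: SyntheticConfig) -> dict[str, int]:
    """Per-activity session counts: the study's counts at n=40, else proportional."""
    counts = {}
    for name, meta in config.taxonomy.items():
        if config.n_participants == 40:
            c = meta.n_participants
        else:
            c = max(1, round(meta.n_participants * config.n_participants / 40))
        counts[name] = min(c, config.n_participants)
    return counts


def participant_profiles(config: SyntheticConfig) -> list[ParticipantProfile]:
    rng = _rng(config.seed, 1)
    width = max(2, len(str(config.n_participants)))
    return [
        ParticipantProfile(
            participant_id=f"P{i + 1:0{width}d}",
            amplitude_scale=float(rng.lognormal(0.0, 0.15)),
            tempo_scale=float(rng.lognormal(0.0, 0.08)),
        )
        for i in range(config.n_participants)
    ]


def generate_benchmark(config: SyntheticConfig) -> BenchmarkBundle:
    """Generate the full paired-device benchmark for a configuration.

    For every (participant, assigned activity): a ground-truth signal, one
    recording per device, and a MET value. At the default n=40 the
    activity-to-participant assignment honours the study's per-activity
    participant counts (178 sessions in total).
    """
    participants = participant_profiles(config)
    counts = _activity_counts(config)
    sessions: list[Session] = []
    for a_idx, (name, meta) in enumerate(config.taxonomy.items()):
        model = config.models[name]
        chosen = _rng(config.seed, 2, a_idx).permutation(config.n_participants)[: counts[name]]
        for p_idx in sorted(int(i) for i in chosen):
            participant = participants[p_idx]
            truth = simulate_activity(
                meta, model, participant,
                seed=_session_seed(config.seed, a_idx, p_idx, 0),
                rate=config.reference_rate,
            )
            recordings = {
                dev.name: record_with_device(
                    truth, dev, seed=_session_seed(config.seed, a_idx, p_idx, 3 + d_idx)
                )
                for d_idx, dev in enumerate(config.devices)
            }
            met = simulate_mets(
                meta, participant, config.met_noise_sd,
                seed=_session_seed(config.seed, a_idx, p_idx, 2),
                anchor=model.met_anchor,
            )
            sessions.append(
                Session(
                    participant=participant,
                    meta=meta,
                    truth=truth,
                    recordings=recordings,
                    met=met,
                )
            )
    return BenchmarkBundle(sessions=sessions, config=config)


def _session_seed(seed: int, a_idx: int, p_idx: int, stream: int) -> int:
    # a deterministic, collision-free small-integer key for the substream
    return int(np.random.SeedSequence([seed, a_idx, p_idx, stream]).generate_state(1)[0] % (2**31))


def _slug(text: str) -> str:
    return text.lower().replace(" ", "_")


def _session_filename(session: Session, device: str) -> str:
    return f"{session.participant_id}_{_slug(session.activity_name)}_{device}.csv"


def write_benchmark(bundle: BenchmarkBundle, out_dir) -> Path:
    """Write a benchmark as a directory of delimited-text files.

    One acceleration file per (session, device), a sessions manifest, the
    taxonomy, and the generating configuration echoed as YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for session in bundle.sessions:
        for device, rec in session.recordings.items():
            write_accel_csv(rec, out / _session_filename(session, device))
    bundle.manifest().to_csv(out / "manifest.csv", index=False)
    save_taxonomy(bundle.config.taxonomy, out / "activity_taxonomy.csv")
    cfg = bundle.config
    echo = {
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "met_noise_sd": cfg.met_noise_sd,
        "reference_rate": cfg.reference_rate,
        "devices": [
            {
                "name": d.name,
                "sampling_rate": d.sampling_rate,
                "dynamic_range": d.dynamic_range,
                "gain": d.gain,
                "misalignment_deg": list(d.misalignment) if d.misalignment else None,
                "noise_sd": d.noise_sd,
            }
            for d in cfg.devices
        ],
        "activities": {
            name: {
                "kind": m.kind,
                "base_frequency": m.base_frequency,
                "amplitude": m.amplitude,
                "noise_sd": m.noise_sd,
                "met_anchor": m.met_anchor,
                "n_sub_actions": len(m.action_pool),
            }
            for name, m in cfg.models.items()
        },
    }
    (out / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=False))
    return out
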