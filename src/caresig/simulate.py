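"""Synthetic bedside-recording generator.

The real study population — nursing-home residents with limited mobility
and vocality — cannot be redistributed, so this module synthesizes
labeled, synchronized skeleton + EEG records with the statistical
structure the downstream classifiers assume: each of the nine
help-requirement classes couples a characteristic joint-trajectory motif
("hand near the mouth", "knee up", ...) with a characteristic profile of
relative EEG band power (δ, θ, α, β) across the eight electrodes.

Two deliberate ambiguities mirror how information is split across
modalities in practice:

* *drinking/eating* and *defecation/urination* share a motion motif and
  differ only in their EEG profile (thirst vs. hunger, and so on);
* *standing/walking* and *sleeping/nothing* share an EEG profile and
  differ only in motion.

A motion-only or EEG-only classifier therefore has a hard accuracy
ceiling on this data, while a fused classifier does not — the property
the multimodal architectures are meant to exploit.

Class counts default to the study's dataset composition (1800 records
over 9 classes).  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    EEG_CHANNELS,
    JOINT_INDEX,
    JOINT_NAMES,
    EEGRecord,
    Record,
    SessionRecord,
    SessionRecording,
    SkeletonSequence,
)
from .exceptions import ConfigurationError, InputError, SamplingError

# --------------------------------------------------------------------------
# resting posture (seated patient, meters; x right, y up, z toward sensor)

RESTING_POSTURE: dict[str, tuple[float, float, float]] = {
    "head": (0.00, 0.70, 0.05),
    "shoulder_center": (0.00, 0.50, 0.03),
    "spine": (0.00, 0.25, 0.02),
    "hip_center": (0.00, 0.00, 0.00),
    "left_shoulder": (-0.18, 0.48, 0.02),
    "right_shoulder": (0.18, 0.48, 0.02),
    "left_elbow": (-0.24, 0.25, 0.08),
    "right_elbow": (0.24, 0.25, 0.08),
    "left_wrist": (-0.22, 0.05, 0.18),
    "right_wrist": (0.22, 0.05, 0.18),
    "left_hand": (-0.21, 0.02, 0.24),
    "right_hand": (0.21, 0.02, 0.24),
    "left_hip": (-0.10, -0.02, 0.00),
    "right_hip": (0.10, -0.02, 0.00),
    "left_knee": (-0.12, -0.05, 0.45),
    "right_knee": (0.12, -0.05, 0.45),
    "left_ankle": (-0.12, -0.45, 0.48),
    "right_ankle": (0.12, -0.45, 0.48),
    "left_foot": (-0.12, -0.50, 0.58),
    "right_foot": (0.12, -0.50, 0.58),
}


def resting_frame() -> np.ndarray:
    """The fixed resting posture as a (20, 3) array in joint order."""
    return np.array([RESTING_POSTURE[j] for j in JOINT_NAMES], dtype=float)


# EEG synthesis bands (Hz).  The sinusoid frequencies are drawn inside
# slightly narrowed ranges so that even a 2 s record contains full cycles
# and the band decomposition can separate them cleanly.
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
_SYNTH_RANGES: dict[str, tuple[float, float]] = {
    "delta": (0.6, 2.8),
    "theta": (4.2, 6.8),
    "alpha": (8.2, 11.8),
    "beta": (13.0, 28.0),
}
_SINES_PER_BAND = 3
EEG_BASE_AMPLITUDE_UV = 10.0  # microvolts per unit profile weight
#: microvolts of white noise per unit of the (coordinate-scale) noise knob
EEG_NOISE_SCALE = 150.0

#: Noise presets for the shared coordinate/signal noise knob (meters of
#: per-coordinate jitter; EEG noise scales with EEG_NOISE_SCALE).
NOISE_PRESETS: dict[str, float] = {
    "zero": 0.0,
    "low": 0.01,
    "moderate": 0.03,
    "high": 0.08,
}


@dataclass(frozen=True)
class MotionMotif:
    """Parameterized joint-trajectory template for one activity class.

    ``offsets`` maps the moved joints to their displacement from the
    resting posture toward the class's target region (e.g. hand → mouth);
    the moved joints additionally oscillate along ``osc_axis`` with the
    given amplitude (m) and frequency (Hz).
    """

    offsets: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    amplitude: float = 0.0
    frequency: float = 1.0
    osc_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    @property
    def target_joint(self) -> str | None:
        return next(iter(self.offsets), None)


@dataclass(frozen=True)
class ActivityClassSpec:
    """One help-requirement class: label, motion motif, EEG profile.

    ``eeg_profile`` has shape (8 channels, 4 bands) of nonnegative
    relative band-power weights in the order of ``EEG_CHANNELS`` ×
    ``BAND_NAMES``.  ``duration_range`` is in seconds; activities in this
    setting take a few seconds, so the minimum is 2 s.
    """

    label: str
    motion_motif: MotionMotif
    eeg_profile: np.ndarray
    duration_range: tuple[float, float] = (2.0, 3.0)

    def __post_init__(self) -> None:
        profile = np.asarray(self.eeg_profile, dtype=float)
        object.__setattr__(self, "eeg_profile", profile)
        if profile.shape != (len(EEG_CHANNELS), len(BAND_NAMES)):
            raise ConfigurationError(
                f"eeg_profile must have shape (8, 4), got {profile.shape}"
            )
        if np.any(profile < 0):
            raise ConfigurationError("eeg_profile weights must be nonnegative")
        if self.duration_range[0] < 2.0:
            raise ConfigurationError("activity durations are at least 2 s")
        for joint in self.motion_motif.offsets:
            if joint not in JOINT_INDEX:
                raise ConfigurationError(f"unknown joint in motion motif: {joint!r}")


def _profile(flat: float = 0.2, **bands) -> np.ndarray:
    """Build an (8, 4) profile: a flat floor plus per-band channel weights.

    ``bands`` maps a band name to {channel: weight}.
    """
    p = np.full((len(EEG_CHANNELS), len(BAND_NAMES)), flat, dtype=float)
    for band, channels in bands.items():
        b = BAND_NAMES.index(band)
        for ch, w in channels.items():
            p[EEG_CHANNELS.index(ch), b] = w
    return p


_FLAT_PROFILE = _profile(flat=0.3)  # resting: flat broadband activity

_HAND_TO_MOUTH = MotionMotif(
    offsets={"right_hand": (-0.17, 0.58, -0.12), "right_wrist": (-0.16, 0.52, -0.10)},
    amplitude=0.02,
    frequency=0.8,
    osc_axis=(0.0, 1.0, 0.0),
)
_HEAD_SHAKE = MotionMotif(
    offsets={"head": (0.0, 0.0, 0.0)},
    amplitude=0.06,
    frequency=1.0,
    osc_axis=(1.0, 0.0, 0.0),
)

_AROUSED_PROFILE = _profile(beta={"F3": 1.0, "F4": 1.0, "C3": 1.0, "C4": 1.0})


def default_class_specs() -> list[ActivityClassSpec]:
    """The nine-class registry used throughout the package.

    Movement motifs follow the class descriptions (hand near the cheek,
    open arms, knee up, hand near the mouth, head movement, hand
    movement, none); EEG profiles encode the paired mental state as
    band-power patterns.  See the module docstring for the deliberate
    cross-modal ambiguities.
    """
    return [
        ActivityClassSpec(
            label="sleeping",
            motion_motif=MotionMotif(
                offsets={"right_hand": (-0.13, 0.56, -0.14), "right_wrist": (-0.12, 0.50, -0.12)},
                amplitude=0.01,
                frequency=0.3,
            ),
            eeg_profile=_FLAT_PROFILE,  # drowsy ≈ resting baseline
        ),
        ActivityClassSpec(
            label="standing",
            motion_motif=MotionMotif(
                offsets={
                    "left_hand": (-0.22, 0.45, -0.05),
                    "left_wrist": (-0.20, 0.40, -0.05),
                    "right_hand": (0.22, 0.45, -0.05),
                    "right_wrist": (0.20, 0.40, -0.05),
                },
                amplitude=0.03,
                frequency=0.6,
                osc_axis=(0.0, 1.0, 0.0),
            ),
            eeg_profile=_AROUSED_PROFILE,
        ),
        ActivityClassSpec(
            label="walking",
            motion_motif=MotionMotif(
                offsets={"left_knee": (0.0, 0.25, -0.05), "left_ankle": (0.0, 0.25, -0.10)},
                amplitude=0.08,
                frequency=1.2,
                osc_axis=(0.0, 1.0, 0.0),
            ),
            eeg_profile=_AROUSED_PROFILE.copy(),  # same arousal state as standing
        ),
        ActivityClassSpec(
            label="drinking",
            motion_motif=_HAND_TO_MOUTH,
            eeg_profile=_profile(alpha={"O1": 1.0, "O2": 1.0, "T5": 1.0, "T6": 1.0}),
        ),
        ActivityClassSpec(
            label="eating",
            motion_motif=replace(_HAND_TO_MOUTH),  # same motif: hand near the mouth
            eeg_profile=_profile(theta={"F3": 1.0, "F4": 1.0}),
        ),
        ActivityClassSpec(
            label="defecation",
            motion_motif=_HEAD_SHAKE,
            eeg_profile=_profile(beta={"T5": 1.0, "T6": 1.0}, delta={"C3": 0.8, "C4": 0.8}),
        ),
        ActivityClassSpec(
            label="urination",
            motion_motif=replace(_HEAD_SHAKE),  # same motif: head movement
            eeg_profile=_profile(alpha={"C3": 1.0, "C4": 1.0}, theta={"T5": 0.8, "T6": 0.8}),
        ),
        ActivityClassSpec(
            label="calling_doctor",
            motion_motif=MotionMotif(
                offsets={"right_hand": (0.05, 0.75, 0.05), "right_wrist": (0.05, 0.65, 0.05)},
                amplitude=0.10,
                frequency=1.5,
                osc_axis=(1.0, 0.0, 0.0),
            ),
            eeg_profile=_profile(beta={ch: 1.0 for ch in EEG_CHANNELS}),
        ),
        ActivityClassSpec(
            label="nothing",
            motion_motif=MotionMotif(),  # resting posture only
            eeg_profile=_FLAT_PROFILE.copy(),
        ),
    ]


#: Dataset composition: records per class in the study's training set.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "sleeping": 192,
    "standing": 198,
    "walking": 202,
    "drinking": 208,
    "eating": 193,
    "defecation": 207,
    "urination": 215,
    "calling_doctor": 185,
    "nothing": 200,
}


@dataclass
class GeneratorConfig:
    """Configuration for dataset / session generation.

    ``noise_sd`` is the per-coordinate Gaussian jitter of the skeleton in
    meters; EEG white noise scales from the same knob (see
    ``EEG_NOISE_SCALE``).  Defaults reproduce the study's composition:
    1800 records over the nine classes.
    """

    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    skeleton_rate: float = 30.0
    eeg_rate: float = 250.0
    noise_sd: float = NOISE_PRESETS["moderate"]
    seed: int = 0
    gap_duration: float = 1.0
    leading_gap: bool = False

    def __post_init__(self) -> None:
        if self.skeleton_rate <= 0 or self.eeg_rate <= 0:
            raise ConfigurationError("rates must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        known = {s.label for s in default_class_specs()}
        unknown = set(self.class_counts) - known
        if unknown:
            raise ConfigurationError(f"unknown class labels: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigurationError("class counts must be nonnegative")


# --------------------------------------------------------------------------
# stream generators


def _ramp(t: np.ndarray, rise: float = 0.5) -> np.ndarray:
    """Smooth 0→1 onset over ``rise`` seconds (activities start from rest)."""
    return np.clip(t / rise, 0.0, 1.0)


def generate_skeleton_stream(
    spec: ActivityClassSpec,
    duration: float,
    rate: float,
    noise_sd: float,
    seed: int,
) -> SkeletonSequence:
    """Generate one record's skeleton stream.

    The motif's joints move from the resting posture toward the target
    region and oscillate there; every coordinate gets independent
    Gaussian noise of standard deviation ``noise_sd`` meters.
    """
    if duration <= 0 or rate <= 0:
        raise InputError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration * rate))
    t = np.arange(n) / rate
    frames = np.broadcast_to(resting_frame(), (n, len(JOINT_NAMES), 3)).copy()

    motif = spec.motion_motif
    if motif.offsets:
        phase = rng.uniform(0.0, 2 * np.pi)
        freq = motif.frequency * rng.uniform(0.85, 1.15)  # per-record tempo jitter
        ramp = _ramp(t)
        osc = motif.amplitude * np.sin(2 * np.pi * freq * t + phase) * ramp
        axis = np.asarray(motif.osc_axis, dtype=float)
        for joint, offset in motif.offsets.items():
            idx = JOINT_INDEX[joint]
            frames[:, idx, :] += ramp[:, None] * np.asarray(offset, dtype=float)
            frames[:, idx, :] += osc[:, None] * axis
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    return SkeletonSequence(t, frames)


def generate_eeg_stream(
    spec: ActivityClassSpec,
    duration: float,
    rate: float,
    noise_sd: float,
    seed: int,
) -> EEGRecord:
    """Generate one record's 8-channel EEG stream.

    Each channel is a sum over the four bands of a small mixture of
    band-limited sinusoids whose amplitude is proportional to the class's
    profile weight for that channel and band, plus white noise.  The rate
    must be at least 64 samples/s so the β band (up to 30 Hz) is resolved.
    """
    if duration <= 0:
        raise InputError("duration must be positive")
    if rate < 64:
        raise SamplingError(f"EEG rate must be >= 64 samples/s, got {rate}")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration * rate))
    t = np.arange(n) / rate
    data = np.zeros((n, len(EEG_CHANNELS)))
    for ci in range(len(EEG_CHANNELS)):
        for bi, band in enumerate(BAND_NAMES):
            w = spec.eeg_profile[ci, bi]
            lo, hi = _SYNTH_RANGES[band]
            freqs = rng.uniform(lo, hi, size=_SINES_PER_BAND)
            phases = rng.uniform(0.0, 2 * np.pi, size=_SINES_PER_BAND)
            amps = rng.uniform(0.5, 1.0, size=_SINES_PER_BAND)
            # equal total power per draw: the class's band power is then
            # set by its profile weight alone, not by the mixture draw
            amps /= np.sqrt((amps**2).sum())
            if w == 0:
                continue  # draws above keep the stream deterministic per seed
            comp = np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])
            data[:, ci] += w * EEG_BASE_AMPLITUDE_UV * comp @ amps
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd * EEG_NOISE_SCALE, size=data.shape)
    return EEGRecord(t, data, rate)


def _spec_registry() -> dict[str, ActivityClassSpec]:
    return {s.label: s for s in default_class_specs()}


def generate_record(
    spec: ActivityClassSpec, config: GeneratorConfig, duration: float, seed: int
) -> Record:
    """Generate one synchronized skeleton+EEG record of the given class."""
    skel = generate_skeleton_stream(spec, duration, config.skeleton_rate, config.noise_sd, seed)
    eeg = generate_eeg_stream(spec, duration, config.eeg_rate, config.noise_sd, seed + 1)
    return Record(skel, eeg, spec.label)


def generate_dataset(config: GeneratorConfig | None = None) -> list[Record]:
    """Generate the full labeled dataset (default: the 1800-record composition).

    Per-class record counts equal ``config.class_counts`` exactly and the
    output is byte-identical for a fixed seed.  Record order is shuffled.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    registry = _spec_registry()
    records: list[Record] = []
    for label in DEFAULT_CLASS_COUNTS:  # fixed class order for determinism
        count = config.class_counts.get(label, 0)
        spec = registry[label]
        for _ in range(count):
            duration = rng.uniform(*spec.duration_range)
            seed = int(rng.integers(0, 2**31 - 2))
            records.append(generate_record(spec, config, duration, seed))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def generate_continuous_session(config: GeneratorConfig | None = None) -> SessionRecording:
    """Generate one continuous session: activities in random order with
    resting ("nothing") gaps between them.

    The per-timepoint ground truth is recoverable from the stored record
    intervals; the gaps carry the resting posture and flat EEG.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    registry = _spec_registry()
    nothing = registry["nothing"]

    labels: list[str] = []
    for label in DEFAULT_CLASS_COUNTS:
        labels.extend([label] * config.class_counts.get(label, 0))
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    skel_parts: list[SkeletonSequence] = []
    eeg_parts: list[EEGRecord] = []
    session_records: list[SessionRecord] = []
    t0 = 0.0

    def _append_gap(duration: float) -> None:
        nonlocal t0
        if duration <= 0:
            return
        seed = int(rng.integers(0, 2**31 - 2))
        rec = generate_record(nothing, config, duration, seed)
        skel_parts.append(SkeletonSequence(rec.skeleton.timestamps + t0, rec.skeleton.data))
        eeg_parts.append(EEGRecord(rec.eeg.timestamps + t0, rec.eeg.data, rec.eeg.rate))
        t0 += duration

    if config.leading_gap:
        _append_gap(config.gap_duration)
    for i, label in enumerate(labels):
        if i > 0:
            _append_gap(config.gap_duration)
        spec = registry[label]
        duration = rng.uniform(*spec.duration_range)
        seed = int(rng.integers(0, 2**31 - 2))
        rec = generate_record(spec, config, duration, seed)
        skel = SkeletonSequence(rec.skeleton.timestamps + t0, rec.skeleton.data)
        eeg = EEGRecord(rec.eeg.timestamps + t0, rec.eeg.data, rec.eeg.rate)
        skel_parts.append(skel)
        eeg_parts.append(eeg)
        session_records.append(SessionRecord(skel, eeg, label, t0, t0 + duration))
        t0 += duration

    if not skel_parts:
        _append_gap(max(config.gap_duration, 2.0))
    skeleton = SkeletonSequence(
        np.concatenate([p.timestamps for p in skel_parts]),
        np.concatenate([p.data for p in skel_parts]),
    )
    eeg = EEGRecord(
        np.concatenate([p.timestamps for p in eeg_parts]),
        np.concatenate([p.data for p in eeg_parts]),
        config.eeg_rate,
    )
    return SessionRecording(skeleton, eeg, session_records, sync_marker=0.0)
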