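"""In-memory containers for the two synchronized bedside streams.

A recording of one help-requirement event consists of a skeleton stream
(20 named joints tracked by a depth sensor, 3-D coordinates in meters)
and an 8-channel EEG stream (scalp potentials in microvolts at a fixed
sampling rate).  Both carry timestamps in seconds on a shared clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

#: The 20 joints of the first-generation Kinect skeleton, the only
#: widely used 20-joint tracking convention.
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "shoulder_center",
    "spine",
    "hip_center",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hand",
    "right_hand",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_foot",
    "right_foot",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

#: 10-20 system electrode sites used by the 8-channel headset.
EEG_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "T5", "T6", "O1", "O2")


@dataclass
class SkeletonSequence:
    """Timestamped frames of 20 named 3-D joints for one record.

    Parameters
    ----------
    timestamps : ndarray, shape (n_frames,)
        Strictly increasing times in seconds.
    data : ndarray, shape (n_frames, 20, 3)
        Joint coordinates in meters, ordered as :data:`JOINT_NAMES`.
    """

    timestamps: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (len(JOINT_NAMES), 3):
            raise InputError(
                f"skeleton data must have shape (n, 20, 3), got {self.data.shape}"
            )
        if self.timestamps.shape != (self.data.shape[0],):
            raise InputError("timestamps and frames disagree in length")
        if self.n_frames > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InputError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of one joint, shape (n_frames, 3)."""
        return self.data[:, JOINT_INDEX[name], :]

    def slice_time(self, start: float, stop: float) -> "SkeletonSequence":
        """Frames with start <= t < stop (times kept on the global clock)."""
        m = (self.timestamps >= start - 1e-9) & (self.timestamps < stop - 1e-9)
        return SkeletonSequence(self.timestamps[m], self.data[m])


@dataclass
class EEGRecord:
    """One record's 8-channel EEG stream.

    Parameters
    ----------
    timestamps : ndarray, shape (n_samples,)
    data : ndarray, shape (n_samples, 8)
        Microvolts, channels ordered as :data:`EEG_CHANNELS`.
    rate : float
        Sampling rate in samples/s.
    """

    timestamps: np.ndarray
    data: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(EEG_CHANNELS):
            raise InputError(
                f"EEG data must have shape (n, 8), got {self.data.shape}"
            )
        if self.timestamps.shape != (self.data.shape[0],):
            raise InputError("timestamps and samples disagree in length")
        if self.rate <= 0:
            raise InputError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, EEG_CHANNELS.index(name)]

    def slice_time(self, start: float, stop: float) -> "EEGRecord":
        m = (self.timestamps >= start - 1e-9) & (self.timestamps < stop - 1e-9)
        return EEGRecord(self.timestamps[m], self.data[m], self.rate)


@dataclass
class Record:
    """One labeled help-requirement event: both streams plus its label."""

    skeleton: SkeletonSequence
    eeg: EEGRecord
    label: str


@dataclass
class SessionRecord:
    """One activity event inside a continuous session."""

    skeleton: SkeletonSequence
    eeg: EEGRecord
    label: str
    start: float
    end: float


@dataclass
class SessionRecording:
    """A continuous session: full streams plus the activity intervals.

    ``records`` holds the labeled activity events with their [start, end)
    intervals on the session clock; the stretches between them are resting
    ("nothing") time.  ``sync_marker`` stores the offset of the
    synchronization pulse at the start of the recording; no timing
    correction is applied from it.
    """

    skeleton: SkeletonSequence
    eeg: EEGRecord
    records: list[SessionRecord] = field(default_factory=list)
    sync_marker: float = 0.0

    @property
    def duration(self) -> float:
        if self.skeleton.n_frames > 1:
            dt = float(np.diff(self.skeleton.timestamps).mean())
            return float(self.skeleton.timestamps[-1]) + dt
        return 0.0

    def label_at(self, start: float, end: float, nothing_label: str = "nothing") -> str:
        """Ground-truth label for a window by majority temporal overlap.

        The window gets an activity's label when that activity covers more
        than half of the window; an exact half-coverage tie goes to the
        earlier activity; otherwise the window is resting time.
        """
        length = end - start
        best_overlap = 0.0
        best_label = nothing_label
        for rec in self.records:  # time-ordered: earlier record wins exact ties
            overlap = max(0.0, min(end, rec.end) - max(start, rec.start))
            if overlap > best_overlap + 1e-9:
                best_overlap = overlap
                best_label = rec.label
        if best_overlap > length / 2 - 1e-9 and best_overlap > 0:
            return best_label
        return nothing_label
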