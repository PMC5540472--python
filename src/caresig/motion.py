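"""Motion feature extraction from skeleton sequences.

The pipeline follows the system's depth-image branch: every frame's 20
joints are re-expressed relative to the spine joint (making the features
invariant to where the patient sits in sensor coordinates), six body
regions are summarized by their center, direction and distance from the
spine, the record is cut into three ordered segments to capture how the
posture evolves over the few seconds an activity takes, and the result
is flattened into a fixed 200-dimensional vector that is min-max scaled
to [0, 1] with statistics fitted on the training folds only.

200-d layout (raw, before scaling):
  [0:126)    per segment (3) × region (6): segment-mean center xyz,
             its unit direction xyz, and its distance from the spine
  [126:162)  inter-segment region-center displacements (s2−s1, s3−s2):
             region (6) × displacement (2) × xyz
  [162:180)  per segment × region: mean frame-to-frame region speed (m/s)
  [180:200)  per joint (20): whole-record displacement norm (last−first)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import JOINT_INDEX, SkeletonSequence
from .exceptions import InputError
from .scaling import MinMaxScaler
from .segmentation import segment_slices

MOTION_DIM = 200

#: The six body regions and their member joints.  The regions are the
#: cervical area, the two wrists, the crotch, and the two knees; each is
#: summarized by the centroid of a small set of adjacent joints.
REGION_MEMBERS: dict[str, tuple[str, ...]] = {
    "cervical": ("head", "shoulder_center"),
    "left_wrist": ("left_wrist", "left_hand"),
    "right_wrist": ("right_wrist", "right_hand"),
    "crotch": ("hip_center", "left_hip", "right_hip"),
    "left_knee": ("left_knee", "left_ankle"),
    "right_knee": ("right_knee", "right_ankle"),
}
REGION_NAMES: tuple[str, ...] = tuple(REGION_MEMBERS)
_REGION_IDX = [
    np.array([JOINT_INDEX[j] for j in members]) for members in REGION_MEMBERS.values()
]


@dataclass(frozen=True)
class RegionDescriptor:
    """Spine-relative summary of one body region in one frame."""

    region: str
    center: np.ndarray  # (3,)
    direction: np.ndarray  # (3,), unit norm (zero vector at the origin)
    distance: float


def normalize_skeleton(seq: SkeletonSequence) -> SkeletonSequence:
    """Re-express every frame with the spine joint as the origin.

    Idempotent, and an isometry within each frame: inter-joint distances
    are unchanged.
    """
    spine = seq.data[:, JOINT_INDEX["spine"], :]
    return SkeletonSequence(seq.timestamps, seq.data - spine[:, None, :])


def _region_centers(seq: SkeletonSequence) -> np.ndarray:
    """Per-frame region centroids, shape (n_frames, 6, 3)."""
    return np.stack([seq.data[:, idx, :].mean(axis=1) for idx in _REGION_IDX], axis=1)


def _directions(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions and norms; a zero-norm center gets the zero direction."""
    dist = np.linalg.norm(centers, axis=-1)
    safe = np.where(dist == 0, 1.0, dist)
    return centers / safe[..., None], dist


def compute_region_descriptors(seq: SkeletonSequence) -> list[list[RegionDescriptor]]:
    """Per-frame list of the six region descriptors (spine-relative)."""
    centers = _region_centers(seq)
    directions, distances = _directions(centers)
    out = []
    for f in range(seq.n_frames):
        out.append(
            [
                RegionDescriptor(
                    REGION_NAMES[r],
                    centers[f, r],
                    directions[f, r],
                    float(distances[f, r]),
                )
                for r in range(len(REGION_NAMES))
            ]
        )
    return out


def segment_record(seq: SkeletonSequence, k: int = 3) -> list[SkeletonSequence]:
    """Split a record into ``k`` contiguous subsequences (earlier take the
    remainder); concatenating them reproduces the original frame order."""
    slices = segment_slices(seq.n_frames, k)
    return [SkeletonSequence(seq.timestamps[s], seq.data[s]) for s in slices]


def raw_motion_features(seq: SkeletonSequence) -> np.ndarray:
    """The unscaled 200-dimensional motion feature vector of one record."""
    if seq.n_frames < 3:
        raise InputError("motion features need at least 3 frames")
    norm = normalize_skeleton(seq)
    centers = _region_centers(norm)  # (n, 6, 3)
    slices = segment_slices(norm.n_frames, 3)

    parts: list[np.ndarray] = []
    seg_means = []
    for s in slices:
        mean_c = centers[s].mean(axis=0)  # (6, 3)
        seg_means.append(mean_c)
        direction, dist = _directions(mean_c)
        parts.append(np.column_stack([mean_c, direction, dist[:, None]]).ravel())
    seg_means = np.stack(seg_means)  # (3, 6, 3)

    parts.append((seg_means[1] - seg_means[0]).ravel())
    parts.append((seg_means[2] - seg_means[1]).ravel())

    speeds = np.zeros((3, len(REGION_NAMES)))
    for si, s in enumerate(slices):
        if s.stop - s.start >= 2:
            dc = np.diff(centers[s], axis=0)  # (m-1, 6, 3)
            dt = np.diff(norm.timestamps[s])[:, None]
            speeds[si] = (np.linalg.norm(dc, axis=-1) / dt).mean(axis=0)
    parts.append(speeds.ravel())

    parts.append(np.linalg.norm(norm.data[-1] - norm.data[0], axis=-1))

    vec = np.concatenate(parts)
    assert vec.shape == (MOTION_DIM,)
    return vec


def extract_motion_features(
    seq: SkeletonSequence, scaler: MinMaxScaler | None = None
) -> np.ndarray:
    """200-d motion feature vector; scaled to [0, 1] when a fitted scaler
    (from the training set) is given, raw otherwise."""
    vec = raw_motion_features(seq)
    if scaler is not None:
        vec = scaler.transform(vec[None, :])[0]
    return vec


class MotionFeatureExtractor:
    """Fits the [0, 1] scaler on training records and transforms any record."""

    def __init__(self) -> None:
        self.scaler = MinMaxScaler()

    @staticmethod
    def raw_matrix(seqs: list[SkeletonSequence]) -> np.ndarray:
        return np.stack([raw_motion_features(s) for s in seqs])

    def fit(self, seqs: list[SkeletonSequence]) -> "MotionFeatureExtractor":
        self.scaler.fit(self.raw_matrix(seqs))
        return self

    def transform(self, seqs: list[SkeletonSequence]) -> np.ndarray:
        return self.scaler.transform(self.raw_matrix(seqs))

    def fit_transform(self, seqs: list[SkeletonSequence]) -> np.ndarray:
        return self.scaler.fit_transform(self.raw_matrix(seqs))
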