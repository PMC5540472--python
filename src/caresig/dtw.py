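"""Dynamic-time-warping 1-nearest-neighbor baseline.

Classic unconstrained DTW: dynamic programming over the alignment grid
with steps {(1,0), (0,1), (1,1)} and Euclidean local cost, no band
constraint.  The classifier is 1-NN over all training records used as
templates, on the skeleton stream rendered as a per-frame series of the
six region descriptors (42-d per frame), temporally downsampled to a
fixed number of frames for tractability.
"""

from __future__ import annotations

import numpy as np

from .containers import SkeletonSequence
from .exceptions import InputError
from .motion import _directions, _region_centers, normalize_skeleton

DEFAULT_SERIES_FRAMES = 12


def _as_series(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2 or a.shape[0] == 0:
        raise InputError("a feature series must be a nonempty (length, dim) array")
    return a


def dtw_distance(a, b) -> float:
    """DTW distance between two vector series (scalar series allowed)."""
    a, b = _as_series(a), _as_series(b)
    if a.shape[1] != b.shape[1]:
        raise InputError("series dimensions differ")
    # local cost matrix, then the usual cumulative recursion
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt((diff**2).sum(axis=-1))
    la, lb = cost.shape
    D = np.full((la + 1, lb + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, la + 1):
        row = D[i]
        prev = D[i - 1]
        for j in range(1, lb + 1):
            row[j] = cost[i - 1, j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(D[la, lb])


def dtw_distance_matrix(
    queries: np.ndarray, templates: np.ndarray, chunk: int = 90
) -> np.ndarray:
    """DTW distances between every query and template, shape (nq, nt).

    Both stacks must share a common series length L and dimension d
    (shape (n, L, d)); the recursion is vectorized over all pairs with a
    rolling-row table, and queries are chunked to bound memory.
    """
    queries = np.asarray(queries, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if queries.ndim != 3 or templates.ndim != 3 or queries.shape[1:] != templates.shape[1:]:
        raise InputError("stacks must share shape (n, L, d)")
    nq, L, _ = queries.shape
    nt = templates.shape[0]
    out = np.empty((nq, nt))
    for s in range(0, nq, chunk):
        Q = queries[s : s + chunk]  # (c, L, d)
        # squared-distance expansion avoids a (c, nt, L, L, d) intermediate
        q2 = (Q**2).sum(-1)[:, None, :, None]
        t2 = (templates**2).sum(-1)[None, :, None, :]
        cross = np.einsum("qid,tjd->qtij", Q, templates)
        cost = np.sqrt(np.maximum(q2 + t2 - 2 * cross, 0.0))  # (c, nt, L, L)
        prev = np.full((cost.shape[0], nt, L + 1), np.inf)
        prev[:, :, 0] = 0.0
        for i in range(1, L + 1):
            cur = np.full_like(prev, np.inf)
            for j in range(1, L + 1):
                cur[:, :, j] = cost[:, :, i - 1, j - 1] + np.minimum(
                    np.minimum(prev[:, :, j], cur[:, :, j - 1]), prev[:, :, j - 1]
                )
            prev = cur
        out[s : s + chunk] = prev[:, :, L]
    return out


def _class_order_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index of each label in the sorted class list (for tie-breaking)."""
    classes = np.array(sorted(set(np.asarray(labels).tolist())))
    return np.searchsorted(classes, labels), classes


def dtw_classify(query, templates: list, labels: list):
    """Label of the nearest template; exact distance ties go to the
    template with the lowest class index."""
    if len(templates) == 0:
        raise InputError("template set is empty")
    if len(templates) != len(labels):
        raise InputError("templates and labels must align")
    dists = np.array([dtw_distance(query, t) for t in templates])
    class_idx, classes = _class_order_indices(np.asarray(labels))
    best = np.min(dists)
    candidates = np.flatnonzero(dists <= best + 1e-12)
    winner = candidates[np.argmin(class_idx[candidates])]
    return labels[winner]


def skeleton_to_series(
    seq: SkeletonSequence, n_frames: int = DEFAULT_SERIES_FRAMES
) -> np.ndarray:
    """Per-frame 42-d region-descriptor series (center, direction,
    distance × 6 regions), spine-normalized and resampled to a fixed
    frame count."""
    norm = normalize_skeleton(seq)
    centers = _region_centers(norm)  # (n, 6, 3)
    directions, dist = _directions(centers)
    frames = np.concatenate(
        [
            centers.reshape(len(centers), -1),
            directions.reshape(len(centers), -1),
            dist,
        ],
        axis=1,
    )  # (n, 42)
    idx = np.round(np.linspace(0, len(frames) - 1, n_frames)).astype(int)
    return frames[idx]


class DTWClassifier:
    """1-NN DTW over skeleton region-descriptor series."""

    def __init__(self, n_frames: int = DEFAULT_SERIES_FRAMES):
        self.n_frames = n_frames
        self.templates_: np.ndarray | None = None
        self.labels_: np.ndarray | None = None

    def fit(self, series: np.ndarray, labels) -> "DTWClassifier":
        self.templates_ = np.asarray(series, dtype=float)
        self.labels_ = np.asarray(labels)
        self._class_idx, self._classes = _class_order_indices(self.labels_)
        return self

    def predict(self, series: np.ndarray) -> np.ndarray:
        if self.templates_ is None:
            raise InputError("classifier not fitted")
        dists = dtw_distance_matrix(np.asarray(series, dtype=float), self.templates_)
        out = []  # nearest template; exact ties toward the lowest class index
        for qi, row in enumerate(dists):
            m = row.min()
            cand = np.flatnonzero(row <= m + 1e-12)
            out.append(self.labels_[cand[np.argmin(self._class_idx[cand])]])
        return np.asarray(out)
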