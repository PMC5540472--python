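"""Evaluation protocol: framing, metrics, cross-validation, benchmark.

Two dataset protocols are supported.  In the *shuffled* protocol each
labeled record is one sample.  In the *continuous* protocol a whole
session is cut into overlapping frames (default 3 s windows, 50% shift)
and each frame is labeled by the activity covering the majority of its
span ("nothing" when no activity covers more than half).

Metrics come from the k×k confusion matrix: A_g (correctly
distinguished, the trace), A_n (misrecognitions), and N_g (resting time
recognized as an activity, tallied but not entering any formula);
P = 100·A_g/(A_g+A_n) is the overall accuracy, R the macro-averaged
per-class recall ×100, and F1 = 2PR/(P+R).

Cross-validation is stratified 10-fold; feature scalers and all
pretraining are fitted inside each training fold only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import HelpRequestSAE
from .containers import Record, SessionRecording
from .dtw import DTWClassifier, skeleton_to_series
from .eeg import raw_mental_features
from .exceptions import ConfigurationError, InputError
from .motion import raw_motion_features
from .sae import SparsityConfig, TrainConfig
from .scaling import MinMaxScaler
from .simulate import GeneratorConfig, generate_dataset

NOTHING = "nothing"


@dataclass(frozen=True)
class FrameSpec:
    """Sliding-window parameters: 3 s frames, 50% shift by default."""

    frame_length: float = 3.0
    shift_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.frame_length <= 0:
            raise InputError("frame_length must be positive")
        if not 0 < self.shift_fraction <= 1:
            raise InputError("shift_fraction must lie in (0, 1]")


def frame_starts(duration: float, spec: FrameSpec) -> np.ndarray:
    """Window start times: 0, step, 2·step, ... while the window fits."""
    if duration < spec.frame_length - 1e-9:
        raise InputError("session shorter than one frame")
    step = spec.frame_length * spec.shift_fraction
    n = int(np.floor((duration - spec.frame_length) / step + 1e-9)) + 1
    return np.arange(n) * step


def frame_session(session: SessionRecording, spec: FrameSpec | None = None) -> list[Record]:
    """Cut a continuous session into labeled framed records."""
    spec = spec or FrameSpec()
    out = []
    for start in frame_starts(session.duration, spec):
        end = start + spec.frame_length
        label = session.label_at(start, end)
        out.append(
            Record(
                session.skeleton.slice_time(start, end),
                session.eeg.slice_time(start, end),
                label,
            )
        )
    return out


@dataclass
class EvalReport:
    """Confusion matrix and the derived indicators."""

    labels: list
    confusion: np.ndarray
    A_g: int
    A_n: int
    N_g: int
    P: float
    R: float
    F1: float

    def to_dict(self) -> dict:
        return {
            "labels": [str(c) for c in self.labels],
            "confusion": self.confusion.tolist(),
            "A_g": self.A_g,
            "A_n": self.A_n,
            "N_g": self.N_g,
            "P": self.P,
            "R": self.R,
            "F1": self.F1,
        }


def compute_metrics(predictions, truth, labels=None) -> EvalReport:
    """Confusion matrix plus P (accuracy), R (macro recall), F1.

    Macro recall averages per-class recall over the classes present in
    the truth.  N_g counts resting-time samples predicted as an activity
    (zero when no "nothing" class is present).
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or len(truth) == 0:
        raise InputError("predictions and truth must align and be nonempty")
    if labels is None:
        labels = sorted(set(truth.tolist()) | set(predictions.tolist()))
    labels = list(labels)
    idx = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predictions):
        conf[idx[t], idx[p]] += 1

    A_g = int(np.trace(conf))
    A_n = int(conf.sum() - A_g)
    N_g = 0
    if NOTHING in idx:
        r = idx[NOTHING]
        N_g = int(conf[r].sum() - conf[r, r])
    P = 100.0 * A_g / (A_g + A_n)
    present = conf.sum(axis=1) > 0
    recalls = np.diag(conf)[present] / conf.sum(axis=1)[present]
    R = 100.0 * float(recalls.mean())
    F1 = 2 * P * R / (P + R) if P + R > 0 else 0.0
    return EvalReport(labels, conf, A_g, A_n, N_g, P, R, F1)


@dataclass
class CVResult:
    """Per-fold and pooled reports from one cross-validation run."""

    fold_reports: list[EvalReport]
    pooled: EvalReport
    predictions: np.ndarray
    fold_of: np.ndarray
    elapsed_s: float = 0.0


def _take(X, idx):
    if isinstance(X, tuple):
        return tuple(_take(x, idx) for x in X)
    return np.asarray(X)[idx]


def cross_validate(X, y, builder, k_folds: int = 10, seed: int = 0, labels=None) -> CVResult:
    """Stratified k-fold cross-validation with in-fold fitting.

    ``builder(X_train, y_train, seed)`` must return a fitted object with
    ``predict(X_test)``; everything data-dependent (scalers,
    pretraining, refinement) must happen inside the builder, so no
    statistic of a held-out fold can leak into training.
    """
    y = np.asarray(y)
    counts = {c: int((y == c).sum()) for c in set(y.tolist())}
    short = {c: n for c, n in counts.items() if n < k_folds}
    if short:
        raise ConfigurationError(
            f"classes with fewer records than folds: {short}"
        )
    t0 = time.perf_counter()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    predictions = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    fold_reports = []
    for fi, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = builder(_take(X, tr), y[tr], seed + fi)
        pred = model.predict(_take(X, te))
        predictions[te] = pred
        fold_of[te] = fi
        fold_reports.append(compute_metrics(pred, y[te], labels))
    pooled = compute_metrics(predictions, y, labels)
    return CVResult(fold_reports, pooled, predictions, fold_of, time.perf_counter() - t0)


# --------------------------------------------------------------------------
# ready-made builders and the end-to-end benchmark


#: Training sizes used for cross-validated benchmarking.  Full-batch
#: descent on ~1600×280 matrices converges to the ceiling of this data
#: well before the module-level defaults; these shorter schedules keep a
#: full 4-architecture, 10-fold benchmark around a minute per replicate.
BENCH_PRETRAIN = TrainConfig(learning_rate=0.5, max_iters=20)
BENCH_HEAD = TrainConfig(learning_rate=1.0, max_iters=100)
BENCH_REFINE = TrainConfig(learning_rate=1.0, max_iters=50)


class _SAEPredictor:
    def __init__(self, results, motion_scaler, mental_scaler):
        self.results = results
        self.motion_scaler = motion_scaler
        self.mental_scaler = mental_scaler

    def predict(self, X):
        motion_raw, mental_raw = X
        return self.results.predict(
            self.motion_scaler.transform(motion_raw),
            self.mental_scaler.transform(mental_raw),
        )


def sae_builder(
    architecture: str,
    sparsity: SparsityConfig | None = None,
    pretrain: TrainConfig | None = None,
    head: TrainConfig | None = None,
    refine: TrainConfig | None = None,
):
    """Builder over raw (unscaled) feature tuples ``(motion, mental)``.

    Scalers are fitted on the training fold; pretraining and refinement
    use the benchmark schedules unless overridden.
    """

    def build(X_train, y_train, seed):
        motion_raw, mental_raw = X_train
        ms = MinMaxScaler().fit(motion_raw)
        es = MinMaxScaler().fit(mental_raw)
        model = HelpRequestSAE(
            ms.transform(motion_raw), es.transform(mental_raw), y_train, architecture
        )
        results = model.fit(
            sparsity=sparsity or SparsityConfig(),
            pretrain=pretrain or BENCH_PRETRAIN,
            head=head or BENCH_HEAD,
            refine_cfg=refine or BENCH_REFINE,
            seed=seed,
        )
        return _SAEPredictor(results, ms, es)

    return build


def dtw_builder(n_frames: int | None = None):
    """Builder over skeleton region-descriptor series stacks."""

    def build(X_train, y_train, seed):
        clf = DTWClassifier(n_frames or X_train.shape[1])
        return clf.fit(X_train, y_train)

    return build


def extract_feature_arrays(records: list[Record]):
    """Raw (unscaled) motion and mental feature matrices plus labels."""
    motion = np.stack([raw_motion_features(r.skeleton) for r in records])
    mental = np.stack([raw_mental_features(r.eeg) for r in records])
    labels = np.array([r.label for r in records])
    return motion, mental, labels


def benchmark_architectures(
    config: GeneratorConfig | None = None,
    seeds=(0,),
    architectures=("single_modal_eeg", "single_modal_skeleton", "early_fusion", "late_fusion"),
    include_dtw: bool = True,
    k_folds: int = 10,
    dtw_series_frames: int = 12,
) -> dict:
    """Generate data and cross-validate every architecture (and DTW).

    Returns ``{"accuracy": {name: mean pooled P}, "recall": ...,
    "f1": ..., "per_seed": ...}`` averaged over the generator seeds.
    """
    base = config or GeneratorConfig()
    per_seed: dict[str, list[dict]] = {}
    for seed in seeds:
        cfg = GeneratorConfig(
            class_counts=dict(base.class_counts),
            skeleton_rate=base.skeleton_rate,
            eeg_rate=base.eeg_rate,
            noise_sd=base.noise_sd,
            seed=seed,
        )
        records = generate_dataset(cfg)
        motion, mental, y = extract_feature_arrays(records)
        runs: dict[str, CVResult] = {}
        for arch in architectures:
            runs[arch] = cross_validate(
                (motion, mental), y, sae_builder(arch), k_folds=k_folds, seed=seed
            )
        if include_dtw:
            series = np.stack(
                [skeleton_to_series(r.skeleton, dtw_series_frames) for r in records]
            )
            runs["dtw"] = cross_validate(
                series, y, dtw_builder(), k_folds=k_folds, seed=seed
            )
        per_seed[str(seed)] = {
            name: {"P": res.pooled.P, "R": res.pooled.R, "F1": res.pooled.F1,
                   "elapsed_s": res.elapsed_s}
            for name, res in runs.items()
        }
    names = list(next(iter(per_seed.values())))
    summary = {
        metric: {
            name: float(np.mean([per_seed[s][name][metric] for s in per_seed]))
            for name in names
        }
        for metric in ("P", "R", "F1")
    }
    return {
        "accuracy": summary["P"],
        "recall": summary["R"],
        "f1": summary["F1"],
        "per_seed": per_seed,
        "n_records": sum(base.class_counts.values()),
        "k_folds": k_folds,
    }
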