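"""Generator tests: stream shapes, class structure, determinism, sessions."""

import numpy as np
import pytest
from scipy.signal import periodogram

import caresig
from caresig.containers import EEG_CHANNELS, JOINT_INDEX
from caresig.exceptions import ConfigurationError, SamplingError
from caresig.simulate import (
    DEFAULT_CLASS_COUNTS,
    ActivityClassSpec,
    GeneratorConfig,
    MotionMotif,
    _profile,
    generate_continuous_session,
    generate_dataset,
    generate_eeg_stream,
    generate_skeleton_stream,
    resting_frame,
)
from tests.conftest import small_counts


@pytest.mark.parametrize("duration,rate,expected", [(3, 30, 90), (2.5, 30, 75), (3, 250, 750)])
def test_skeleton_frame_count(class_specs, duration, rate, expected):
    seq = generate_skeleton_stream(class_specs["drinking"], duration, rate, 0.0, 0)
    assert seq.n_frames == expected


def test_nothing_class_is_resting_posture_at_zero_noise(class_specs):
    seq = generate_skeleton_stream(class_specs["nothing"], 3, 30, 0.0, 3)
    assert np.array_equal(seq.data, np.broadcast_to(resting_frame(), seq.data.shape))


def test_drinking_brings_hand_to_head(class_specs):
    """The hand-to-mouth motif moves the right hand closer to the head
    than resting; verified from the emitted coordinates."""

    def hand_head_distance(label):
        seq = generate_skeleton_stream(class_specs[label], 3, 30, 0.0, 5)
        d = seq.joint("right_hand") - seq.joint("head")
        return np.linalg.norm(d, axis=1).mean()

    assert hand_head_distance("drinking") < hand_head_distance("nothing")


def test_unknown_joint_is_configuration_error():
    with pytest.raises(ConfigurationError):
        ActivityClassSpec(
            label="bad",
            motion_motif=MotionMotif(offsets={"left_flipper": (0, 0, 0)}),
            eeg_profile=np.zeros((8, 4)),
        )


def test_eeg_sample_count(class_specs):
    rec = generate_eeg_stream(class_specs["drinking"], 3, 250, 0.0, 0)
    assert rec.data.shape == (750, len(EEG_CHANNELS))


def test_eeg_zero_profile_zero_noise_is_silent():
    spec = ActivityClassSpec("nothing", MotionMotif(), np.zeros((8, 4)))
    rec = generate_eeg_stream(spec, 3, 250, 0.0, 0)
    assert np.all(rec.data == 0)


def test_eeg_rate_below_64_rejected(class_specs):
    with pytest.raises(SamplingError):
        generate_eeg_stream(class_specs["drinking"], 3, 50, 0.0, 0)


def test_alpha_heavy_profile_dominates_periodogram():
    """A class whose profile loads the α band should put most spectral
    power in 8–12 Hz — checked on the emitted signal itself."""
    spec = ActivityClassSpec(
        "alpha_probe",
        MotionMotif(),
        _profile(flat=0.02, alpha={ch: 1.0 for ch in EEG_CHANNELS}),
    )
    rec = generate_eeg_stream(spec, 4, 250, 0.0, 11)
    f, pxx = periodogram(rec.data[:, 0], fs=rec.rate)

    def band_power(lo, hi):
        return pxx[(f >= lo) & (f <= hi)].sum()

    alpha = band_power(8, 12)
    for lo, hi in [(0.1, 3), (4, 7), (13, 30)]:
        assert alpha > band_power(lo, hi)


def test_dataset_counts_and_determinism():
    cfg = GeneratorConfig(class_counts=small_counts(4), seed=9)
    recs = generate_dataset(cfg)
    labels = [r.label for r in recs]
    assert len(recs) == 36
    for label in small_counts(4):
        assert labels.count(label) == 4
    recs2 = generate_dataset(GeneratorConfig(class_counts=small_counts(4), seed=9))
    for a, b in zip(recs, recs2):
        assert a.label == b.label
        assert np.array_equal(a.skeleton.data, b.skeleton.data)
        assert np.array_equal(a.eeg.data, b.eeg.data)


def test_default_composition_sums_to_1800():
    assert sum(DEFAULT_CLASS_COUNTS.values()) == 1800


def test_session_duration_additivity():
    cfg = GeneratorConfig(
        class_counts={"drinking": 1, "walking": 1}, seed=1, gap_duration=1.0
    )
    session = generate_continuous_session(cfg)
    d1 = session.records[0].end - session.records[0].start
    d2 = session.records[1].end - session.records[1].start
    assert session.duration == pytest.approx(d1 + 1.0 + d2, abs=0.1)


def test_session_with_no_activities_is_resting_only():
    cfg = GeneratorConfig(class_counts={}, seed=1)
    session = generate_continuous_session(cfg)
    assert session.records == []
    assert session.duration > 0


def test_session_labels_round_trip():
    """Querying each stored [start, end) interval recovers the label used
    at generation time."""
    cfg = GeneratorConfig(class_counts=small_counts(2), seed=3)
    session = generate_continuous_session(cfg)
    assert len(session.records) == 18
    for rec in session.records:
        assert session.label_at(rec.start, rec.end) == rec.label
        skel = session.skeleton.slice_time(rec.start, rec.end)
        assert skel.n_frames == rec.skeleton.n_frames


def test_csv_round_trip(tmp_path, small_dataset):
    from caresig import io as cio

    recs = small_dataset[:3]
    cio.write_records(recs, tmp_path / "d")
    back = cio.read_records(tmp_path / "d")
    assert [r.label for r in back] == [r.label for r in recs]
    for a, b in zip(recs, back):
        np.testing.assert_allclose(a.skeleton.data, b.skeleton.data, atol=1e-12)
        np.testing.assert_allclose(a.eeg.data, b.eeg.data, atol=1e-10)


def test_session_csv_round_trip(tmp_path):
    from caresig import io as cio

    cfg = GeneratorConfig(class_counts={"drinking": 2, "eating": 1}, seed=2)
    session = generate_continuous_session(cfg)
    cio.write_session(session, tmp_path / "s")
    back = cio.read_session(tmp_path / "s")
    assert [r.label for r in back.records] == [r.label for r in session.records]
    np.testing.assert_allclose(back.skeleton.data, session.skeleton.data, atol=1e-12)


def _motif_parameter_estimates(records):
    """Per-record estimates of the generating motif parameters: mean
    joint offsets from the resting posture (motion motif) and mean band
    amplitude per channel/band (EEG profile)."""
    from caresig.eeg import BAND_NAMES as EEG_BANDS
    from caresig.eeg import bandpass_decompose

    rest = resting_frame()
    rows = []
    for rec in records:
        offsets = (rec.skeleton.data - rest).mean(axis=0).ravel()  # (60,)
        decomp = bandpass_decompose(rec.eeg)
        powers = np.concatenate(
            [np.sqrt((decomp.band(b) ** 2).mean(axis=0)) for b in EEG_BANDS]
        )  # (32,) amplitudes ∝ profile weights
        rows.append(np.concatenate([offsets, powers]))
    return np.stack(rows)


def test_zero_noise_motif_parameters_fully_separable():
    """With no noise the classes are distinguishable by construction:
    1-NN on recovered motif parameters is perfect, and adding noise
    never helps (averaged over seeds)."""
    from sklearn.neighbors import KNeighborsClassifier

    from caresig.scaling import MinMaxScaler

    def knn_accuracy(noise, seed):
        cfg = GeneratorConfig(class_counts=small_counts(4), noise_sd=noise, seed=seed)
        recs = generate_dataset(cfg)
        X = MinMaxScaler().fit_transform(_motif_parameter_estimates(recs))
        y = np.array([r.label for r in recs])
        knn = KNeighborsClassifier(1)
        hits = 0
        idx = np.arange(len(y))
        for i in idx:
            knn.fit(X[idx != i], y[idx != i])
            hits += knn.predict(X[i : i + 1])[0] == y[i]
        return hits / len(y)

    assert knn_accuracy(0.0, 0) == 1.0
    seeds = range(10)
    acc_mid = np.mean([knn_accuracy(0.05, s) for s in seeds])
    acc_high = np.mean([knn_accuracy(0.30, s) for s in seeds])
    assert 1.0 >= acc_mid >= acc_high


def test_feature_table_round_trip(tmp_path, small_dataset):
    from caresig import io as cio
    from caresig.evaluate import extract_feature_arrays
    from caresig.scaling import MinMaxScaler

    m, e, y = extract_feature_arrays(small_dataset[:6])
    ms = MinMaxScaler().fit(m)
    cio.write_feature_table(tmp_path / "f", m, e, y, motion_scaler=ms)
    m2, e2, y2, scalers = cio.read_feature_table(tmp_path / "f")
    np.testing.assert_allclose(m2, m, rtol=1e-12)
    np.testing.assert_allclose(e2, e, rtol=1e-10)
    assert list(y2) == list(y)
    np.testing.assert_allclose(scalers["motion_scaler"].min_, ms.min_)
    assert scalers["mental_scaler"] is None
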