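"""Mental (EEG) feature extraction.

Each 8-channel record is band-pass filtered into the four conventional
bands — δ (0.1–3 Hz), θ (4–7 Hz), α (8–12 Hz), β (12–30 Hz) — with
zero-phase 4th-order Butterworth filters (the δ band is realized as a
0.1 Hz high-pass followed by a 3 Hz low-pass).  Band edges are taken as
printed: α and β meet at 12 Hz, and the 3–4 Hz stretch between δ and θ
belongs to no band.

Features are statistics of instantaneous band power (the squared band
signal; power rather than amplitude, switchable in principle by feeding
a different statistic).  80-d layout (raw, before scaling):

  [0:32)   per channel (8) × band (4): whole-record mean band power
  [32:64)  per channel × band: whole-record variance of band power
  [64:72)  per channel: broadband mean power over the middle of the
           record's three divisions
  [72:80)  per channel: broadband power variance over the same division

The three-way division reuses the same remainder rule as the motion
branch.  Scaling to [0, 1] uses a min-max scaler fitted on training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EEG_CHANNELS, EEGRecord
from .exceptions import InputError, SamplingError
from .scaling import MinMaxScaler
from .segmentation import segment_slices

MENTAL_DIM = 80

#: Band edges in Hz, as conventionally defined for this system.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.1, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}
BAND_NAMES: tuple[str, ...] = tuple(BAND_EDGES)

_FILTER_ORDER = 4


@dataclass
class BandDecomposition:
    """Band-limited versions of all 8 channels: band name → (n, 8) array."""

    bands: dict[str, np.ndarray]
    rate: float

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]


def _band_sos(band: str, rate: float) -> list[np.ndarray]:
    lo, hi = BAND_EDGES[band]
    nyq = rate / 2
    if band == "delta":
        # 0.1 Hz high-pass + 3 Hz low-pass: a direct 0.1–3 Hz band-pass
        # at typical rates is numerically fragile near DC.
        return [
            signal.butter(_FILTER_ORDER, lo / nyq, btype="highpass", output="sos"),
            signal.butter(_FILTER_ORDER, hi / nyq, btype="lowpass", output="sos"),
        ]
    return [
        signal.butter(_FILTER_ORDER, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    ]


def bandpass_decompose(rec: EEGRecord) -> BandDecomposition:
    """Zero-phase band-pass filtering of all channels into the four bands.

    Requires at least 64 samples/s (to resolve the β band) and 1 s of
    signal (so the forward-backward filter has room for its edges).
    """
    if rec.rate < 64:
        raise SamplingError(f"rate must be >= 64 samples/s, got {rec.rate}")
    if rec.n_samples < rec.rate:
        raise InputError("need at least 1 s of signal to decompose")
    bands = {}
    for band in BAND_NAMES:
        x = rec.data
        for si, sos in enumerate(_band_sos(band, rec.rate)):
            # the 0.1 Hz high-pass has a ~10 s time constant; maximal
            # padding keeps its edge transient out of short records
            padlen = rec.n_samples - 1 if band == "delta" and si == 0 else None
            x = signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
        bands[band] = x
    return BandDecomposition(bands, rec.rate)


def raw_mental_features(
    rec: EEGRecord, decomp: BandDecomposition | None = None
) -> np.ndarray:
    """The unscaled 80-dimensional mental feature vector of one record.

    ``decomp`` may be supplied to reuse a precomputed band decomposition
    (or to inject synthetic band series in tests).
    """
    if rec.n_samples < 3:
        raise InputError("mental features need at least 3 samples per channel")
    if decomp is None:
        decomp = bandpass_decompose(rec)

    n_ch = len(EEG_CHANNELS)
    means = np.empty((n_ch, len(BAND_NAMES)))
    variances = np.empty((n_ch, len(BAND_NAMES)))
    for bi, band in enumerate(BAND_NAMES):
        power = decomp.band(band) ** 2  # instantaneous power, (n, 8)
        means[:, bi] = power.mean(axis=0)
        variances[:, bi] = power.var(axis=0)

    mid = segment_slices(rec.n_samples, 3)[1]
    broadband = rec.data[mid] ** 2
    vec = np.concatenate(
        [
            means.ravel(),
            variances.ravel(),
            broadband.mean(axis=0),
            broadband.var(axis=0),
        ]
    )
    assert vec.shape == (MENTAL_DIM,)
    return vec


def extract_mental_features(
    rec: EEGRecord,
    scaler: MinMaxScaler | None = None,
    decomp: BandDecomposition | None = None,
) -> np.ndarray:
    """80-d mental feature vector; scaled to [0, 1] when a fitted scaler
    (from the training set) is given, raw otherwise."""
    vec = raw_mental_features(rec, decomp)
    if scaler is not None:
        vec = scaler.transform(vec[None, :])[0]
    return vec


class MentalFeatureExtractor:
    """Fits the [0, 1] scaler on training records and transforms any record."""

    def __init__(self) -> None:
        self.scaler = MinMaxScaler()

    @staticmethod
    def raw_matrix(recs: list[EEGRecord]) -> np.ndarray:
        return np.stack([raw_mental_features(r) for r in recs])

    def fit(self, recs: list[EEGRecord]) -> "MentalFeatureExtractor":
        self.scaler.fit(self.raw_matrix(recs))
        return self

    def transform(self, recs: list[EEGRecord]) -> np.ndarray:
        return self.scaler.transform(self.raw_matrix(recs))

    def fit_transform(self, recs: list[EEGRecord]) -> np.ndarray:
        return self.scaler.fit_transform(self.raw_matrix(recs))
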