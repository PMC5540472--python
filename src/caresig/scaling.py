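"""Min-max feature scaling to [0, 1].

The autoencoders reconstruct through a sigmoid, so inputs must live in
[0, 1].  The scaler is fitted on training folds only; transformed values
are clipped to [0, 1] so out-of-range test-set values cannot leak
outside the sigmoid's codomain.  Constant training columns map to 0.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError, NotFittedError


class MinMaxScaler:
    """Columnwise min-max scaler with clipping on transform."""

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.range_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise InputError("scaler expects a nonempty 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise InputError("features must be finite")
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        rng[rng == 0] = 1.0  # constant columns → 0 after shifting
        self.range_ = rng
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise NotFittedError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        return np.clip((X - self.min_) / self.range_, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        if self.min_ is None:
            raise NotFittedError("scaler not fitted")
        return {"min": self.min_.tolist(), "range": self.range_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        s = cls()
        s.min_ = np.asarray(d["min"], dtype=float)
        s.range_ = np.asarray(d["range"], dtype=float)
        return s
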