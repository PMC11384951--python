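"""Leakage-safe encoding of heterogeneous clinical features.

Discrete features are target-encoded against the severity total with a
smoothed (prior-count) category mean; every feature is then standard-scaled.
Both steps fit on training rows only, so transforming held-out rows never
uses their own statistics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted


class SofaTargetEncoder(BaseEstimator, TransformerMixin):
    """Smoothed target-mean encoding of discrete columns.

    A category ``c`` with training targets ``t_1..t_n`` encodes as
    ``(sum(t) + smoothing * prior) / (n + smoothing)`` where ``prior`` is
    the global training target mean; unseen categories map to the prior.

    Parameters
    ----------
    columns : list of str
        Discrete columns to encode; other columns pass through unchanged.
    smoothing : float, default 1.0
        Pseudo-count weight pulling sparse categories toward the prior.
    """

    def __init__(self, columns: list[str] | None = None, smoothing: float = 1.0):
        self.columns = columns
        self.smoothing = smoothing

    def fit(self, X: pd.DataFrame, y):
        if len(X) == 0:
            raise ValueError("cannot fit a target encoder on an empty table")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("target length does not match table length")
        cols = list(self.columns) if self.columns is not None else []
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"columns not in table: {missing}")
        self.prior_ = float(y.mean())
        self.mapping_ = {}
        s = float(self.smoothing)
        for col in cols:
            grouped = pd.Series(y).groupby(X[col].to_numpy()).agg(["sum", "count"])
            enc = (grouped["sum"] + s * self.prior_) / (grouped["count"] + s)
            self.mapping_[col] = enc.to_dict()
        self.columns_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mapping_")
        out = X.copy()
        for col in self.columns_:
            if col not in out.columns:
                raise ValueError(f"column {col!r} absent at transform time")
            out[col] = (
                out[col].map(self.mapping_[col]).fillna(self.prior_).astype(float)
            )
        return out


class StateSpaceEncoder(BaseEstimator, TransformerMixin):
    """Target-encode discrete columns, then standard-scale every column.

    The fitted transform maps a feature table into the continuous scaled
    space in which distances are computed.  Zero-variance columns are scaled
    by 1 (they become identically zero), never NaN.

    Parameters
    ----------
    discrete_columns : list of str
        Columns to target-encode before scaling.
    smoothing : float, default 1.0
        Smoothing weight of the target encoder.
    """

    def __init__(
        self, discrete_columns: list[str] | None = None, smoothing: float = 1.0
    ):
        self.discrete_columns = discrete_columns
        self.smoothing = smoothing

    def fit(self, X: pd.DataFrame, y):
        self.encoder_ = SofaTargetEncoder(
            columns=self.discrete_columns, smoothing=self.smoothing
        ).fit(X, y)
        encoded = self.encoder_.transform(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.scaler_ = StandardScaler().fit(encoded.to_numpy(dtype=float))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scaler_")
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns absent at transform time: {missing}")
        encoded = self.encoder_.transform(X[list(self.feature_names_in_)])
        scaled = self.scaler_.transform(encoded.to_numpy(dtype=float))
        if not np.all(np.isfinite(scaled)):
            raise ValueError("non-finite values produced by encoding")
        return pd.DataFrame(scaled, columns=self.feature_names_in_, index=X.index)

    def inverse_scale(self, X: pd.DataFrame) -> pd.DataFrame:
        """Undo the scaling step (target encoding is not invertible)."""
        check_is_fitted(self, "scaler_")
        raw = self.scaler_.inverse_transform(X.to_numpy(dtype=float))
        return pd.DataFrame(raw, columns=self.feature_names_in_, index=X.index)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted state for reproducibility."""
        check_is_fitted(self, "scaler_")
        state = {
            "smoothing": self.smoothing,
            "columns": list(self.feature_names_in_),
            "discrete_columns": list(self.encoder_.columns_),
            "prior": self.encoder_.prior_,
            "mapping": {
                col: {str(k): v for k, v in m.items()}
                for col, m in self.encoder_.mapping_.items()
            },
            "center": self.scaler_.mean_.tolist(),
            "spread": self.scaler_.scale_.tolist(),
        }
        text = json.dumps(state, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
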