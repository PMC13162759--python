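"""Uniformly sampled scalar traces (pupil, luminance, annotations).

The whole pipeline moves 1-D signals around at three rates: 60 Hz (pupil),
1 Hz (annotations, luminance, power envelopes) and 200 Hz (EEG, which has
its own container in :mod:`narousal.montage`).  ``TimeSeries1D`` is the
shared carrier: values plus a sampling rate plus an explicit missing-value
mask, so that "missing" never has to be smuggled through NaNs implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeSeries1D:
    """A uniformly sampled scalar trace.

    Parameters
    ----------
    values : ndarray
        Sample values. Entries where ``missing_mask`` is True may be NaN.
    fs : float
        Sampling rate in Hz; must be positive.
    missing_mask : ndarray of bool, optional
        True marks a missing sample. Defaults to all-False (fully observed).
    """

    values: np.ndarray
    fs: float
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries1D values must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask and values must have equal length")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if len(self) else 0.0

    def times(self) -> np.ndarray:
        """Sample times in seconds, first sample at t = 0."""
        return np.arange(self.values.size) / self.fs

    def copy(self) -> "TimeSeries1D":
        return TimeSeries1D(self.values.copy(), self.fs, self.missing_mask.copy())

    # -- plain-text round trip -------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.times(), "value": self.values})
        df.loc[self.missing_mask, "value"] = np.nan
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "TimeSeries1D":
        df = pd.read_csv(path)
        values = df["value"].to_numpy(dtype=float)
        if fs is None:
            t = df["time_s"].to_numpy(dtype=float)
            if t.size < 2:
                raise ValueError("cannot infer sampling rate from fewer than 2 samples")
            fs = 1.0 / float(np.median(np.diff(t)))
        missing = ~np.isfinite(values)
        return cls(values, float(fs), missing)


@dataclass
class LuminanceSeries:
    """Mean screen luminance per second, in 8-bit grey levels (0-255)."""

    values: np.ndarray
    fs: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("luminance values must be one-dimensional")
        if np.any((self.values < 0) | (self.values > 255)):
            raise ValueError("luminance values must lie within [0, 255]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs
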