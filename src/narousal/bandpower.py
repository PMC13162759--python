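"""Time-resolved band power and its correlation with arousal.

EEG is cut into consecutive non-overlapping 1 s epochs (a 20-minute
recording gives exactly 1200).  Per epoch and channel: linear detrend,
Hann-tapered periodogram, mean power over the band's bins, log10.  The
log-power series is then Gaussian-smoothed (40 s window, matching the
pupil pipeline's kernel) and z-scored per channel, leaving the phasic
power fluctuations on the same footing as the z-scored arousal
trajectory.  Their coupling is the dot product of the two standardized
vectors divided by N-1 — algebraically the Pearson correlation
coefficient, kept in dot-product form because that is the quantity the
cluster statistics consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import EegRecording
from .smoothing import gaussian_smooth, zscore
from .trajectories import ArousalTrajectory

_LOG_FLOOR = 1e-20


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band; ``fractional`` weights bins by partial overlap.

    Binary bands take bins with lo <= f < hi (the band with the highest
    upper edge in a set also includes hi, so a partition has no
    double-counted or orphaned edge bin).  The low-IAF band is 1 Hz wide
    on a 1 Hz grid, so it is realized with fractional-overlap weights
    instead.
    """

    name: str
    lo: float
    hi: float
    fractional: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got [{self.lo}, {self.hi}]")


def correlation_bands(iaf: float) -> list[BandDefinition]:
    """Band preset for the power-arousal correlation analysis."""
    return [BandDefinition("delta", 1.0, 4.0),
            BandDefinition("theta", 4.0, 7.0),
            BandDefinition("low_iaf", iaf - 1.0, iaf, fractional=True)]


def isc_bands(iaf: float) -> list[BandDefinition]:
    """Band preset for EEG power-envelope ISC (delta starts at 2 Hz)."""
    return [BandDefinition("delta", 2.0, 4.0),
            BandDefinition("theta", 4.0, 7.0),
            BandDefinition("low_iaf", iaf - 1.0, iaf, fractional=True)]


@dataclass
class BandPowerSeries:
    """Per-channel band-power envelope at 1 s resolution."""

    values: np.ndarray          # (n_channels, n_epochs)
    band: BandDefinition
    stage: str                  # raw_log | smoothed | zscored
    epoch_s: float = 1.0

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _band_weights(freqs: np.ndarray, band: BandDefinition,
                  top_edge: float) -> np.ndarray:
    if band.fractional:
        df = freqs[1] - freqs[0]
        cell_lo = freqs - df / 2.0
        cell_hi = freqs + df / 2.0
        overlap = np.minimum(cell_hi, band.hi) - np.maximum(cell_lo, band.lo)
        return np.maximum(overlap, 0.0)
    w = ((freqs >= band.lo) & (freqs < band.hi)).astype(float)
    if band.hi == top_edge:
        w[np.isclose(freqs, band.hi)] = 1.0
    return w


def epoch_band_power(eeg: EegRecording, bands: list[BandDefinition],
                     epoch_s: float = 1.0) -> dict[str, BandPowerSeries]:
    """Log10 mean band power per channel per consecutive 1 s epoch.

    A trailing partial epoch is dropped with a warning.  Returns one
    ``raw_log``-stage series per band.
    """
    nper = int(round(epoch_s * eeg.fs))
    n_epochs = eeg.n_samples // nper
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    if eeg.n_samples % nper:
        warnings.warn(
            f"dropping a partial final epoch of {eeg.n_samples % nper} "
            "samples", RuntimeWarning)
    x = eeg.data[:, :n_epochs * nper].reshape(eeg.n_channels, n_epochs, nper)
    freqs, pxx = signal.periodogram(x, fs=eeg.fs, window="hann",
                                    detrend="linear", axis=-1)
    if np.any(pxx.sum(axis=-1) <= _LOG_FLOOR):
        warnings.warn("epoch with no power above the numerical floor "
                      "(constant signal?)", RuntimeWarning)
    top_edge = max(b.hi for b in bands)
    out = {}
    for band in bands:
        w = _band_weights(freqs, band, top_edge)
        if w.sum() == 0:
            raise ValueError(f"band {band.name} covers no frequency bins")
        mean_power = (pxx * w).sum(axis=-1) / w.sum()
        out[band.name] = BandPowerSeries(
            np.log10(np.maximum(mean_power, _LOG_FLOOR)), band, "raw_log",
            epoch_s)
    return out


def transform_power(series: BandPowerSeries,
                    smooth_window_s: int = 40) -> BandPowerSeries:
    """Gaussian smoothing along epochs, then per-channel z-scoring."""
    if series.stage != "raw_log":
        raise ValueError(f"expected a raw_log series, got {series.stage!r}")
    smoothed = gaussian_smooth(series.values, window=smooth_window_s)
    sd = smoothed.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"channel {bad} has zero variance; cannot z-score")
    z = zscore(smoothed, axis=1)
    return BandPowerSeries(z, series.band, "zscored", series.epoch_s)


def dot_product_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """dot(zx, zy) / (N - 1) on freshly standardized vectors.

    With sample-SD standardization this equals the Pearson correlation
    coefficient exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length vectors")
    zx = zscore(x)
    zy = zscore(y)
    return float(zx @ zy / (x.size - 1))


def correlate_with_arousal(series: BandPowerSeries,
                           arousal: ArousalTrajectory,
                           max_trim: int = 10) -> np.ndarray:
    """Per-channel correlation of the z-scored envelope with arousal.

    Lengths are trimmed to their common prefix if they differ by at most
    ``max_trim`` epochs (logged); larger mismatches are alignment errors.
    """
    if series.stage != "zscored":
        raise ValueError("series must be at the zscored stage")
    n_env = series.n_epochs
    n_ar = len(arousal)
    if abs(n_env - n_ar) > max_trim:
        raise ValueError(
            f"envelope ({n_env}) and arousal ({n_ar}) lengths differ by "
            f"more than {max_trim} epochs")
    n = min(n_env, n_ar)
    if n_env != n_ar:
        warnings.warn(f"trimming to common length {n} "
                      f"(envelope {n_env}, arousal {n_ar})", RuntimeWarning)
    a = arousal.values[:n]
    return np.array([dot_product_correlation(series.values[c, :n], a)
                     for c in range(series.n_channels)])
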