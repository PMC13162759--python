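"""Pupil-diameter preprocessing: despiking, de-blinking, luminance removal.

The cleaning chain mirrors a standard pupillometry pipeline for 60 Hz
eye-tracker data recorded during movie viewing:

1. drop the first 300 samples (5 s of luminance adaptation);
2. mark large spikes as missing (deviation from a 100-point running
   median greater than 5 median absolute deviations);
3. fill missing samples from the 100-point moving median;
4. mark samples whose first difference exceeds 3 SD of the
   first-difference distribution (two-sided) as missing — the de-blinking
   step — and re-fill as in 3;
5. apply a 100-point median filter.

A subject whose trace is more than 40% missing at any stage is excluded
(raised as :class:`SubjectExcluded`, carrying the stage name).  The
cleaned trace is then linearly resampled onto a uniform 1 Hz grid,
screen luminance is regressed out by ordinary least squares per subject,
and the residuals are smoothed with a 40-sample Gaussian window.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from numpy.lib.stride_tricks import sliding_window_view

from .smoothing import gaussian_smooth
from .timeseries import LuminanceSeries, TimeSeries1D

N_INITIAL_DROP = 300      # samples excluded at trace start (5 s at 60 Hz)
MEDIAN_WINDOW = 100       # running-median and median-filter window, samples
SPIKE_MAD_FACTOR = 5.0    # spike = deviation from running median > 5 MAD
DERIV_SD_FACTOR = 3.0     # de-blink = first difference beyond 3 SD
MISSING_GATE = 0.40       # subject excluded above this missing fraction


class SubjectExcluded(Exception):
    """Raised when a trace exceeds the missingness gate at some stage."""

    def __init__(self, stage: str, fraction: float):
        self.stage = stage
        self.fraction = fraction
        super().__init__(
            f"missing fraction {fraction:.2f} exceeds {MISSING_GATE:.0%} "
            f"at stage {stage!r}")


def frames_to_luminance(frames, frame_rate: float) -> LuminanceSeries:
    """Mean grey level per second from a sequence of RGB frames.

    Frames are converted to grayscale with the Rec. 601 luma weights and
    averaged; per-frame means are then averaged within each whole second
    to give a 1 Hz series.  A trailing partial second is dropped.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise ValueError("frame sequence is empty")
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must be (n, height, width, 3) RGB")
    gray = frames @ np.array([0.299, 0.587, 0.114])
    per_frame = gray.mean(axis=(1, 2))
    fpS = int(round(frame_rate))
    n_sec = per_frame.size // fpS
    if n_sec == 0:
        raise ValueError("need at least one full second of frames")
    per_sec = per_frame[:n_sec * fpS].reshape(n_sec, fpS).mean(axis=1)
    return LuminanceSeries(np.clip(per_sec, 0.0, 255.0))


def _running_median(values: np.ndarray, window: int = MEDIAN_WINDOW) -> np.ndarray:
    """Centered moving median with reflected edges, NaN-tolerant."""
    half_l = (window - 1) // 2
    half_r = window - 1 - half_l
    padded = np.pad(values, (half_l, half_r), mode="reflect")
    win = sliding_window_view(padded, window)
    with np.errstate(all="ignore"):
        med = np.nanmedian(win, axis=1)
    # windows that are all-NaN fall back to the global median
    bad = ~np.isfinite(med)
    if bad.any():
        med[bad] = np.nanmedian(values)
    return med


def _fill_missing(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Replace missing samples by the 100-point moving median."""
    work = values.copy()
    work[missing] = np.nan
    med = _running_median(work)
    out = values.copy()
    out[missing] = med[missing]
    return out


def _gate(missing: np.ndarray, stage: str) -> None:
    frac = float(missing.mean())
    if frac > MISSING_GATE:
        raise SubjectExcluded(stage, frac)


def clean_pupil(raw: TimeSeries1D, qc: dict | None = None) -> TimeSeries1D:
    """Run the five-stage cleaning chain on a raw 60 Hz pupil trace.

    Parameters
    ----------
    raw : TimeSeries1D
        Raw trace; its ``missing_mask`` marks device dropouts.
    qc : dict, optional
        If given, receives per-stage missing fractions under
        ``qc["missing_fraction"]`` for quality-control reporting.

    Returns
    -------
    TimeSeries1D
        Cleaned trace at the input rate, starting 300 samples after the
        raw trace's start; all samples observed (missing repaired).

    Raises
    ------
    ValueError
        If the trace is shorter than the 300-sample exclusion window.
    SubjectExcluded
        If more than 40% of samples are missing at any stage.
    """
    if len(raw) <= N_INITIAL_DROP:
        raise ValueError(
            f"trace has {len(raw)} samples; need more than {N_INITIAL_DROP}")
    fractions: dict[str, float] = {}

    # (1) initial-sample exclusion
    values = raw.values[N_INITIAL_DROP:].copy()
    missing = raw.missing_mask[N_INITIAL_DROP:].copy()
    missing |= ~np.isfinite(values)
    fractions["input"] = float(missing.mean())
    _gate(missing, "input")

    # (2) spike marking: deviation from running median > 5 MAD.  The MAD
    # is floored at 2% of the trace's overall robust scale so that an
    # already-smoothed trace (whose residual MAD is near zero) is not
    # shredded by a threshold of essentially zero.
    work = values.copy()
    work[missing] = np.nan
    med = _running_median(work)
    dev = values - med
    dev_obs = dev[~missing]
    mad = np.median(np.abs(dev_obs - np.median(dev_obs)))
    obs = values[~missing]
    scale_floor = 0.02 * np.median(np.abs(obs - np.median(obs)))
    mad = max(mad, scale_floor)
    if mad > 0:
        missing |= (~np.isnan(dev)) & (np.abs(dev) > SPIKE_MAD_FACTOR * mad)
    fractions["spike_removal"] = float(missing.mean())
    _gate(missing, "spike_removal")

    # (3) moving-median interpolation
    filled = _fill_missing(values, missing)

    # (4) de-blinking on first differences, then re-fill.  The SD gets
    # the same robust-scale floor as the spike threshold: on a smooth
    # (already cleaned) trace the derivative SD collapses and would
    # otherwise flag benign curvature.
    d = np.diff(filled)
    sd = max(d.std(), scale_floor)
    if sd > 0:
        jump = np.abs(d - d.mean()) > DERIV_SD_FACTOR * sd
        blink = np.zeros_like(missing)
        blink[1:] |= jump          # sample after the jump
        blink[:-1] |= jump         # sample before the jump
        missing |= blink
    fractions["deblink"] = float(missing.mean())
    _gate(missing, "deblink")
    filled = _fill_missing(values, missing)
    if qc is not None:
        qc["repaired_mask"] = missing.copy()

    # (5) 100-point median filter
    out = ndimage.median_filter(filled, size=MEDIAN_WINDOW, mode="reflect")
    fractions["output"] = 0.0
    if qc is not None:
        qc["missing_fraction"] = fractions
        qc["excluded"] = False
    return TimeSeries1D(out, raw.fs)


def regress_out(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS of y on x (with intercept); returns residuals, slope, intercept.

    The residuals are exactly orthogonal to x (and to the constant), so
    any linear luminance pathway into the pupil signal is removed.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("regressor and signal must have equal length")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return resid, float(coef[1]), float(coef[0])


def resample_and_regress(clean: TimeSeries1D, luminance: LuminanceSeries,
                         smooth_window_s: int = 40,
                         start_offset_s: float = N_INITIAL_DROP / 60.0,
                         report: dict | None = None) -> TimeSeries1D:
    """1 Hz resampling, luminance regression, Gaussian smoothing.

    The cleaned trace (whose first sample sits at ``start_offset_s`` of
    movie time, after the initial-sample exclusion) is linearly
    interpolated onto the uniform grid 0..duration-1 s defined by the
    luminance series; samples outside its support take the nearest value.
    Luminance is regressed out by per-subject OLS and the residuals are
    smoothed with a ``smooth_window_s``-sample Gaussian window.
    """
    duration = int(round(luminance.duration_s))
    if clean.duration_s + start_offset_s < duration - 1:
        raise ValueError(
            "cleaned trace does not span the luminance series duration")
    grid = np.arange(duration, dtype=float)
    t = start_offset_s + clean.times()
    on_grid = np.interp(grid, t, clean.values)  # clamps = nearest-value ends
    resid, slope, intercept = regress_out(on_grid, luminance.values)
    if report is not None:
        report["luminance_slope"] = slope
        report["luminance_intercept"] = intercept
    smoothed = gaussian_smooth(resid, window=smooth_window_s)
    return TimeSeries1D(smoothed, fs=1.0)
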