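"""Gaussian smoothing with the single kernel convention used pipeline-wide.

Both the pupil trace (after luminance regression) and the log band-power
envelopes are smoothed with a Gaussian moving window of 40 samples at 1 Hz.
The kernel is truncated at the window length, sigma = window / 6, and the
convolution is renormalized at the edges so that a constant input maps to
itself everywhere (no edge droop).
"""

from __future__ import annotations

import numpy as np


def gaussian_kernel(window: int, sigma: float | None = None) -> np.ndarray:
    """Truncated, unit-sum Gaussian kernel spanning ``window`` samples.

    sigma defaults to window / 6 so the truncation sits at +-3 sigma.
    The kernel is realized with an odd tap count (2 * (window // 2) + 1)
    so it is exactly centered — an even tap count would shift every
    output by half a sample and break impulse-response symmetry.
    """
    if window < 1:
        raise ValueError("window must be a positive number of samples")
    if sigma is None:
        sigma = window / 6.0
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(values: np.ndarray, window: int = 40,
                    sigma: float | None = None) -> np.ndarray:
    """Smooth along the last axis with an edge-renormalized Gaussian window.

    Linear and shift-equivariant away from the edges; at the edges the
    kernel mass falling outside the signal is renormalized away, which
    keeps constants invariant.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    k = gaussian_kernel(min(window, max(n - 1, 1)), sigma)

    def _conv1(v: np.ndarray) -> np.ndarray:
        num = np.convolve(v, k, mode="same")
        den = np.convolve(np.ones_like(v), k, mode="same")
        return num / den

    if values.ndim == 1:
        return _conv1(values)
    flat = values.reshape(-1, n)
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        out[i] = _conv1(row)
    return out.reshape(values.shape)


def zscore(values: np.ndarray, axis: int = -1, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD by default)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=axis, keepdims=True)
    sd = values.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a zero-variance signal")
    return (values - mu) / sd
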