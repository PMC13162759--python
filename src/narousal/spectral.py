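"""Spectral parametrization: aperiodic 1/f fit, Gaussian peaks, IAF.

A neural power spectrum mixes periodic peaks with a broadband aperiodic
background.  In log10 power the model is

    S(f) = L(f) + sum_n G_n(f),      L(f) = b - chi * log10(f),

with L a line in log-log space (offset b, exponent chi) and each G_n a
Gaussian (center, height above the aperiodic component, width).  Fitting
is iterative: a peak-resistant line fit, greedy extraction of residual
Gaussians, an aperiodic refit on the peak-removed spectrum, and a final
simultaneous refinement.  Subtracting L from S yields the "flattened"
spectrum on which oscillatory quantities — most importantly the
individual alpha frequency (IAF), the 8-13 Hz peak with the highest
flattened power — are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .clusterstats import Cluster, chain_adjacency, form_clusters, \
    _max_cluster_mass, _neighbor_lists

_LOG_FLOOR = 1e-20  # power floor before log10, avoids -inf on dead bins


@dataclass
class PowerSpectrum:
    """Frequencies (Hz) with log10 power and the grid resolution."""

    freqs: np.ndarray
    power: np.ndarray      # log10 power
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def crop(self, lo: float, hi: float) -> "PowerSpectrum":
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.freqs[m], self.power[m], self.resolution)


@dataclass
class AperiodicComponent:
    """Offset and exponent of the log-log linear background."""

    offset: float
    exponent: float

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError("aperiodic component defined only for f > 0")
        return self.offset - self.exponent * np.log10(freqs)


@dataclass
class GaussianPeak:
    """A periodic peak: center (Hz), height (log10 units), width (Hz SD)."""

    center: float
    height: float
    width: float

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        return self.height * np.exp(
            -0.5 * ((np.asarray(freqs, float) - self.center) / self.width) ** 2)


@dataclass
class SpectralFit:
    """Full decomposition: aperiodic + peaks + flattened residual."""

    aperiodic: AperiodicComponent
    peaks: list[GaussianPeak]
    flattened: PowerSpectrum     # S - L on the fitted range
    fit_error: float             # mean absolute residual of the full model
    freqs: np.ndarray = field(default=None)  # type: ignore

    def model(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, float)
        out = self.aperiodic.evaluate(f)
        for pk in self.peaks:
            out = out + pk.evaluate(f)
        return out


@dataclass
class IafEstimate:
    """Individual alpha frequency and the derived low-alpha band."""

    iaf: float
    low_band: tuple[float, float]

    def __post_init__(self) -> None:
        if not 8.0 <= self.iaf <= 13.0:
            raise ValueError(f"IAF {self.iaf} outside 8-13 Hz")


class NoAlphaPeakError(Exception):
    """No peak found in 8-13 Hz; caller should fall back (e.g., to the
    group-median IAF) rather than silently invent one."""


# ---------------------------------------------------------------------------
# Welch spectra
# ---------------------------------------------------------------------------

def welch_psd(x: np.ndarray, fs: float, window_s: float = 1.28,
              overlap: float = 0.5,
              zero_pad_s: float | None = None) -> PowerSpectrum:
    """Hann-tapered averaged periodogram, log10-scaled.

    ``zero_pad_s`` pads each segment to that length before the FFT,
    refining the frequency grid without changing the underlying
    resolution — a 2 s window padded to 10 s gives a 0.1 Hz grid, as
    used for individual-alpha-frequency detection.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples shorter than the "
            f"{nperseg}-sample window")
    nfft = nperseg if zero_pad_s is None else int(round(zero_pad_s * fs))
    freqs, pxx = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=int(round(nperseg * overlap)),
                              nfft=nfft, detrend="constant", axis=-1)
    if pxx.ndim > 1:
        pxx = pxx.mean(axis=tuple(range(pxx.ndim - 1)))
    power = np.log10(np.maximum(pxx, _LOG_FLOOR))
    return PowerSpectrum(freqs, power, resolution=float(freqs[1] - freqs[0]))


# ---------------------------------------------------------------------------
# aperiodic + peak decomposition
# ---------------------------------------------------------------------------

def _line_fit(log_f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of y on log10 f; returns (offset, exponent)."""
    design = np.column_stack([np.ones_like(log_f), -log_f])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def _robust_line_fit(log_f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Peak-resistant line fit: refit excluding bins far above the line.

    Oscillatory peaks only ever add power, so bins more than 1 SD above
    the first-pass line are treated as peak-contaminated and dropped.
    """
    b, chi = _line_fit(log_f, y)
    resid = y - (b - chi * log_f)
    keep = resid <= resid.std()
    if keep.sum() >= 3:
        b, chi = _line_fit(log_f[keep], y[keep])
    return b, chi


def _fit_one_peak(freqs: np.ndarray, resid: np.ndarray, guess_c: float,
                  guess_h: float, sigma_bounds: tuple[float, float]
                  ) -> GaussianPeak | None:
    """Least-squares Gaussian around the largest residual point."""
    lo_s, hi_s = sigma_bounds
    # half-height extent as the width guess
    half = guess_h / 2.0
    i = int(np.argmin(np.abs(freqs - guess_c)))
    left = i
    while left > 0 and resid[left] > half:
        left -= 1
    right = i
    while right < resid.size - 1 and resid[right] > half:
        right += 1
    fwhm = max(freqs[right] - freqs[left], freqs[1] - freqs[0])
    guess_s = float(np.clip(fwhm / 2.355, lo_s, hi_s))
    window = np.abs(freqs - guess_c) <= max(3.0 * guess_s, 2.0)
    if window.sum() < 4:
        return None
    try:
        popt, _ = optimize.curve_fit(
            lambda f, c, h, w: h * np.exp(-0.5 * ((f - c) / w) ** 2),
            freqs[window], resid[window],
            p0=[guess_c, guess_h, guess_s],
            bounds=([freqs[0], 0.0, lo_s], [freqs[-1], np.inf, hi_s]),
            maxfev=2000)
    except RuntimeError:
        return None
    return GaussianPeak(center=float(popt[0]), height=float(popt[1]),
                        width=float(popt[2]))


def fit_spectral_model(spectrum: PowerSpectrum,
                       f_range: tuple[float, float] = (2.0, 40.0),
                       max_peaks: int = 6,
                       width_limits: tuple[float, float] = (1.0, 20.0),
                       min_height: float = 0.15) -> SpectralFit:
    """Decompose a log10 power spectrum into aperiodic + Gaussian peaks.

    Fixed (knee-free) aperiodic mode.  ``width_limits`` bound twice the
    Gaussian SD; ``min_height`` (log10 units above the aperiodic fit) is
    the smallest peak worth reporting.
    """
    spec = spectrum.crop(*f_range)
    if spec.freqs.size < 5:
        raise ValueError("fewer than 5 frequency bins in the fit range")
    freqs, y = spec.freqs, spec.power
    log_f = np.log10(freqs)
    sigma_bounds = (width_limits[0] / 2.0, width_limits[1] / 2.0)

    # (1) peak-resistant aperiodic guess
    b, chi = _robust_line_fit(log_f, y)
    resid = y - (b - chi * log_f)

    # (2) greedy Gaussian extraction from the residual
    peaks: list[GaussianPeak] = []
    work = resid.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        if work[i] < min_height:
            break
        pk = _fit_one_peak(freqs, work, freqs[i], float(work[i]), sigma_bounds)
        if pk is None or pk.height < min_height:
            break
        work -= pk.evaluate(freqs)
        peaks.append(pk)

    # (3) aperiodic refit on the peak-removed spectrum
    peakless = y.copy()
    for pk in peaks:
        peakless -= pk.evaluate(freqs)
    b, chi = _robust_line_fit(log_f, peakless)

    # (4) final simultaneous refinement of everything
    if peaks:
        def full_model(f, *params):
            out = params[0] - params[1] * np.log10(f)
            for j in range(len(peaks)):
                c, h, w = params[2 + 3 * j: 5 + 3 * j]
                out = out + h * np.exp(-0.5 * ((f - c) / w) ** 2)
            return out

        p0 = [b, chi]
        lo = [-np.inf, -np.inf]
        hi = [np.inf, np.inf]
        for pk in peaks:
            p0 += [pk.center, pk.height, pk.width]
            lo += [freqs[0], 0.0, sigma_bounds[0]]
            hi += [freqs[-1], np.inf, sigma_bounds[1]]
        try:
            popt, _ = optimize.curve_fit(full_model, freqs, y, p0=p0,
                                         bounds=(lo, hi), maxfev=5000)
            b, chi = float(popt[0]), float(popt[1])
            peaks = [GaussianPeak(float(popt[2 + 3 * j]),
                                  float(popt[3 + 3 * j]),
                                  float(popt[4 + 3 * j]))
                     for j in range(len(peaks))]
            peaks = [pk for pk in peaks if pk.height >= min_height]
        except RuntimeError:
            pass  # keep the sequential estimates

    aperiodic = AperiodicComponent(offset=b, exponent=chi)
    line = aperiodic.evaluate(freqs)
    model = line + sum((pk.evaluate(freqs) for pk in peaks),
                       np.zeros_like(freqs))
    flattened = PowerSpectrum(freqs, y - line, spec.resolution)
    return SpectralFit(aperiodic=aperiodic, peaks=peaks, flattened=flattened,
                       fit_error=float(np.mean(np.abs(y - model))),
                       freqs=freqs)


# ---------------------------------------------------------------------------
# individual alpha frequency
# ---------------------------------------------------------------------------

ALPHA_RANGE = (8.0, 13.0)


def estimate_iaf(resting_spectrum: PowerSpectrum,
                 f_range: tuple[float, float] = (1.0, 40.0)) -> IafEstimate:
    """IAF: frequency of maximal flattened power in 8-13 Hz.

    Requires a high-resolution (0.1 Hz grid) spectrum of the resting
    recording.  A model peak must exist within the alpha range — flat
    spectra raise :class:`NoAlphaPeakError` so the caller can fall back
    to a group-level default instead of reporting a spurious edge value.
    """
    fit = fit_spectral_model(resting_spectrum, f_range=f_range)
    lo, hi = ALPHA_RANGE
    if not any(lo <= pk.center <= hi for pk in fit.peaks):
        raise NoAlphaPeakError(
            "no spectral peak detected within 8-13 Hz; fall back to the "
            "group-median IAF")
    mask = (fit.flattened.freqs >= lo) & (fit.flattened.freqs <= hi)
    sub_f = fit.flattened.freqs[mask]
    iaf = float(sub_f[np.argmax(fit.flattened.power[mask])])
    iaf = float(np.clip(iaf, lo, hi))
    return IafEstimate(iaf=iaf, low_band=(iaf - 1.0, iaf))


# ---------------------------------------------------------------------------
# condition contrasts
# ---------------------------------------------------------------------------

@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float


def aperiodic_contrast(exponents_rest: np.ndarray,
                       exponents_movie: np.ndarray) -> PairedTResult:
    """Paired t-test on per-subject aperiodic exponents (rest vs movie)."""
    a = np.asarray(exponents_rest, dtype=float)
    b = np.asarray(exponents_movie, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired vectors with n >= 3")
    diff = b - a
    if diff.std(ddof=1) < 1e-12 * max(1.0, float(np.abs(diff).max())):
        if np.allclose(diff, 0):
            return PairedTResult(0.0, a.size - 1, 1.0,
                                 float(a.mean()), float(b.mean()))
        raise ValueError("zero-variance nonzero differences: t is degenerate")
    t, p = stats.ttest_rel(b, a)
    return PairedTResult(float(t), a.size - 1, float(p),
                         float(a.mean()), float(b.mean()))


def frequency_cluster_test(flattened_rest: np.ndarray,
                           flattened_movie: np.ndarray,
                           freqs: np.ndarray,
                           f_range: tuple[float, float] = (2.0, 18.0),
                           n_perm: int = 1000, alpha: float = 0.05,
                           seed: int = 0) -> list[Cluster]:
    """Cluster permutation contrast of flattened spectra (movie - rest).

    Per-bin paired t; contiguous same-sign supra-threshold bins form
    clusters with mass sum(|t|); the null retains the maximum cluster
    mass of each of ``n_perm`` per-subject condition-label swaps
    (sign flips of the paired differences).  Cluster p-values are
    add-one corrected and two-tailed by construction (mass is unsigned).
    """
    import warnings as _warnings
    rest = np.asarray(flattened_rest, dtype=float)
    movie = np.asarray(flattened_movie, dtype=float)
    if rest.shape != movie.shape:
        raise ValueError("conditions must have identical (subjects, bins) shape")
    if n_perm < 100:
        _warnings.warn("n_perm < 100 gives a very coarse null", RuntimeWarning)
    freqs = np.asarray(freqs, dtype=float)
    m = (freqs >= f_range[0]) & (freqs <= f_range[1])
    diff = movie[:, m] - rest[:, m]
    n, n_bins = diff.shape
    df = n - 1
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))

    sd = diff.std(axis=0, ddof=1)
    if np.any(sd == 0):
        sd = np.maximum(sd, 1e-300)
    t_obs = diff.mean(axis=0) / (sd / np.sqrt(n))

    adjacency = chain_adjacency(n_bins)
    clusters = form_clusters(t_obs, adjacency, t_crit)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    mm = signs @ diff / n
    ss = np.sum(diff * diff, axis=0)
    var = np.maximum((ss - n * mm * mm) / (n - 1), 1e-300)
    t_null = mm / np.sqrt(var / n)
    neighbors = _neighbor_lists(adjacency)
    null_max = np.array([_max_cluster_mass(t_null[k], neighbors, t_crit)
                         for k in range(n_perm)])
    for cl in clusters:
        cl.p_corrected = float(
            (1.0 + np.sum(null_max >= cl.mass)) / (1.0 + n_perm))
    # attach the frequency extent for reporting
    sub_f = freqs[m]
    for cl in clusters:
        cl.freq_range = (float(sub_f[cl.members[0]]),  # type: ignore[attr-defined]
                         float(sub_f[cl.members[-1]]))
    return clusters
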