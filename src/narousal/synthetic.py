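"""Synthetic naturalistic-viewing cohort with known ground truth.

A single latent arousal trajectory (1 Hz, z-scaled) drives three observable
modalities, mimicking what a movie-viewing cohort produces:

* continuous self-report annotation raters on a 0-250 scale, each a noisy
  copy of the latent trajectory;
* 60 Hz pupil-diameter traces contaminated by screen luminance and by
  blinks, spikes and dropouts, with the artifact-free trace retained so
  cleaning can be scored against truth;
* multichannel EEG whose delta/theta/alpha band amplitudes are modulated
  by the latent trajectory with configurable per-channel coupling signs
  and strengths, on top of a 1/f aperiodic background.

Everything is deterministic given a seed, so a cohort can be regenerated
bit-for-bit from its manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import EegRecording, Montage
from .timeseries import LuminanceSeries, TimeSeries1D

BAND_NAMES = ("delta", "theta", "alpha")

#: Spectral centers/widths (Hz) of the simulated oscillations.  Delta and
#: theta sit mid-band; the alpha center is each subject's individual alpha
#: frequency.  Widths are Gaussian-spectral SDs, so the oscillations are
#: narrowband-filtered noise rather than pure tones.
BAND_SHAPE = {"delta": (2.5, 0.7), "theta": (5.5, 0.8), "alpha": (None, 0.5)}


# ---------------------------------------------------------------------------
# latent trajectory
# ---------------------------------------------------------------------------

@dataclass
class LatentArousal:
    """The shared arousal trajectory all modalities are coupled to."""

    values: np.ndarray  # z-scaled, 1 Hz
    duration_s: int
    seed: int
    smoothness_s: float = 40.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.duration_s:
            raise ValueError("latent length must equal duration in seconds")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values must be finite")

    def upsampled(self, fs: float) -> np.ndarray:
        """Linear interpolation onto an fs-Hz grid covering the duration."""
        t1 = np.arange(self.duration_s, dtype=float)
        t = np.arange(int(round(self.duration_s * fs))) / fs
        return np.interp(t, t1, self.values)

    def sample_and_hold(self, fs: float) -> np.ndarray:
        """Each 1 s value held constant for fs samples."""
        return np.repeat(self.values, int(round(fs)))


def _smooth_gaussian_noise(n: int, smoothness_s: float, fs: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered Gaussian noise, standardized to mean 0 / SD 1.

    Cutoff is 1/smoothness_s Hz (zero-phase 4th-order Butterworth), which
    for smoothness 40 s at 1 Hz leaves a trajectory with lag-1
    autocorrelation well above 0.9.
    """
    white = rng.standard_normal(n + 8 * int(smoothness_s * fs) + 16)
    cutoff = 1.0 / smoothness_s
    nyq = fs / 2.0
    wn = min(cutoff / nyq, 0.98)
    sos = signal.butter(4, wn, output="sos")
    smooth = signal.sosfiltfilt(sos, white)
    # trim the warm-up padding symmetrically
    pad = (smooth.size - n) // 2
    smooth = smooth[pad:pad + n]
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    if sd == 0:
        raise RuntimeError("degenerate latent trajectory (zero variance)")
    return smooth / sd


def generate_latent_arousal(duration_s: int, smoothness_s: float = 40.0,
                            seed: int = 0) -> LatentArousal:
    """Smooth stochastic arousal trajectory at 1 Hz, z-scaled.

    Parameters
    ----------
    duration_s : int
        Movie duration in seconds; must be at least 60.
    smoothness_s : float
        Timescale of the trajectory; the low-pass cutoff is its inverse.
    seed : int
        Seeds the whole trajectory; same seed gives a bitwise-identical one.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be at least 60 seconds")
    if not smoothness_s > 0:
        raise ValueError("smoothness_s must be positive")
    rng = np.random.default_rng(seed)
    values = _smooth_gaussian_noise(int(duration_s), smoothness_s, fs=1.0, rng=rng)
    return LatentArousal(values, int(duration_s), seed, smoothness_s)


# ---------------------------------------------------------------------------
# annotation raters
# ---------------------------------------------------------------------------

def generate_annotation_cohort(latent: LatentArousal, n_subjects: int,
                               fidelity: float, seed: int = 0,
                               scale_center: float = 125.0,
                               scale_gain: float = 45.0) -> list[TimeSeries1D]:
    """Simulated continuous arousal annotations on the 0-250 rating scale.

    Each rater reports ``fidelity * latent + (1 - fidelity) * own noise``
    (the noise being an independent trajectory with the latent's
    smoothness), affinely mapped onto the rating scale and clipped to
    [0, 250].  fidelity 1 makes raters identical; fidelity 0 makes them
    mutually independent.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    if n_subjects < 2:
        raise ValueError("need at least 2 raters (pairwise ISC needs pairs)")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for ss in children:
        rng = np.random.default_rng(ss)
        noise = _smooth_gaussian_noise(latent.duration_s, latent.smoothness_s,
                                       fs=1.0, rng=rng)
        mix = fidelity * latent.values + (1.0 - fidelity) * noise
        values = np.clip(scale_center + scale_gain * mix, 0.0, 250.0)
        out.append(TimeSeries1D(values, fs=1.0))
    return out


# ---------------------------------------------------------------------------
# pupil traces
# ---------------------------------------------------------------------------

@dataclass
class PupilArtifactParams:
    """Rates and shapes of the injected pupil artifacts."""

    blink_rate_per_min: float = 10.0
    blink_duration_ms: tuple[float, float] = (200.0, 400.0)
    blink_ramp_ms: float = 50.0
    blink_floor: float = 0.03      # fraction of baseline during a blink
    spike_rate_per_min: float = 2.0
    spike_amplitude: tuple[float, float] = (0.5, 1.5)  # diameter units
    missing_rate_per_min: float = 0.5
    missing_duration_s: tuple[float, float] = (0.2, 1.0)
    noise_sd: float = 0.05         # white measurement noise, diameter units
    slow_noise_sd: float = 0.25    # idiosyncratic slow arousal, diameter units


@dataclass
class SimulatedPupil:
    """One subject's raw pupil trace plus the retained ground truth."""

    raw: TimeSeries1D
    clean: TimeSeries1D            # baseline + signal + noise, no artifacts
    blink_mask: np.ndarray         # samples altered by injected blinks
    spike_mask: np.ndarray
    injected_missing: np.ndarray
    latent_gain: float             # a in  a * latent
    luminance_gain: float          # b in  - b * luminance


def generate_pupil_cohort(latent: LatentArousal, luminance: LuminanceSeries,
                          n_subjects: int, fs: float = 60.0,
                          artifact_params: PupilArtifactParams | None = None,
                          seed: int = 0, baseline: float = 4.0,
                          latent_gain: float = 0.3,
                          luminance_gain: float = 0.004) -> list[SimulatedPupil]:
    """Pupil traces driven by arousal and contaminated by luminance.

    trace = baseline + a * latent - b * luminance + noise, plus injected
    blinks (brief drops to near-zero with short ramps), single-sample
    spikes and missing runs.  The noise has a fast (measurement) and a
    slow (idiosyncratic arousal) component; the slow part is what keeps
    pupil inter-subject correlation realistically below 1.  The
    artifact-free trace is retained so the cleaning pipeline can be
    scored against it.
    """
    if artifact_params is None:
        artifact_params = PupilArtifactParams()
    if luminance.duration_s != latent.duration_s:
        raise ValueError(
            f"luminance duration ({luminance.duration_s:.0f} s) does not match "
            f"latent duration ({latent.duration_s:.0f} s)")
    p = artifact_params
    n = int(round(latent.duration_s * fs))
    lat_up = latent.upsampled(fs)
    t1 = np.arange(len(luminance), dtype=float)
    lum_up = np.interp(np.arange(n) / fs, t1, luminance.values)

    children = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort = []
    for ss in children:
        rng = np.random.default_rng(ss)
        noise = rng.standard_normal(n) * p.noise_sd
        if p.slow_noise_sd > 0:
            noise = noise + p.slow_noise_sd * _smooth_gaussian_noise(
                n, latent.smoothness_s, fs, rng)
        clean = baseline + latent_gain * lat_up - luminance_gain * lum_up + noise
        raw = clean.copy()
        blink_mask = np.zeros(n, dtype=bool)
        spike_mask = np.zeros(n, dtype=bool)
        miss_mask = np.zeros(n, dtype=bool)

        # blinks: drop to a small fraction of baseline with linear ramps
        n_blinks = rng.poisson(p.blink_rate_per_min * latent.duration_s / 60.0)
        ramp = max(1, int(round(p.blink_ramp_ms / 1000.0 * fs)))
        for _ in range(n_blinks):
            dur = rng.uniform(*p.blink_duration_ms) / 1000.0
            width = max(2 * ramp + 1, int(round(dur * fs)))
            start = rng.integers(0, max(1, n - width))
            depth = np.full(width, p.blink_floor)
            # ramps strictly below baseline so every blink sample is an
            # actual excursion from the clean trace
            depth[:ramp] = np.linspace(1.0, p.blink_floor, ramp + 2)[1:-1]
            depth[-ramp:] = np.linspace(p.blink_floor, 1.0, ramp + 2)[1:-1]
            seg = slice(start, start + width)
            raw[seg] = baseline * depth + noise[seg] * p.blink_floor
            blink_mask[seg] = True

        # isolated spikes
        n_spikes = rng.poisson(p.spike_rate_per_min * latent.duration_s / 60.0)
        for _ in range(n_spikes):
            i = rng.integers(0, n)
            raw[i] += rng.choice([-1.0, 1.0]) * rng.uniform(*p.spike_amplitude)
            spike_mask[i] = True

        # device dropouts
        n_miss = rng.poisson(p.missing_rate_per_min * latent.duration_s / 60.0)
        for _ in range(n_miss):
            dur = rng.uniform(*p.missing_duration_s)
            width = max(1, int(round(dur * fs)))
            start = rng.integers(0, max(1, n - width))
            raw[start:start + width] = np.nan
            miss_mask[start:start + width] = True

        cohort.append(SimulatedPupil(
            raw=TimeSeries1D(raw, fs, miss_mask),
            clean=TimeSeries1D(clean.copy(), fs),
            blink_mask=blink_mask, spike_mask=spike_mask,
            injected_missing=miss_mask,
            latent_gain=latent_gain, luminance_gain=luminance_gain))
    return cohort


def generate_luminance(duration_s: int, seed: int = 0,
                       mean: float = 110.0, sd: float = 35.0,
                       smoothness_s: float = 8.0) -> LuminanceSeries:
    """A plausible movie luminance series: smooth, bounded grey levels."""
    rng = np.random.default_rng(seed)
    z = _smooth_gaussian_noise(int(duration_s), smoothness_s, fs=1.0, rng=rng)
    return LuminanceSeries(np.clip(mean + sd * z, 0.0, 255.0))


# ---------------------------------------------------------------------------
# EEG cohort
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Ground-truth arousal-to-band-power couplings, per channel and band.

    beta[c, b] scales how strongly band b's amplitude envelope on channel c
    follows the latent trajectory; its sign sets the direction.  beta = 0
    leaves the envelope flat, making that channel/band independent of the
    latent.
    """

    beta: np.ndarray               # (n_channels, n_bands)
    bands: tuple[str, ...] = BAND_NAMES

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2 or self.beta.shape[1] != len(self.bands):
            raise ValueError("beta must be (n_channels, n_bands)")
        if np.any(np.abs(self.beta) > 1.0):
            raise ValueError("|beta| must not exceed 1")

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.beta).astype(int)

    @classmethod
    def null(cls, n_channels: int) -> "CouplingSpec":
        return cls(np.zeros((n_channels, len(BAND_NAMES))))

    @classmethod
    def posterior(cls, montage: Montage, channels, beta: float = -0.3,
                  bands=BAND_NAMES) -> "CouplingSpec":
        """Uniform coupling on the named channels for the named bands."""
        mat = np.zeros((montage.n_channels, len(BAND_NAMES)))
        idx = montage.index(channels)
        for b in bands:
            mat[idx, BAND_NAMES.index(b)] = beta
        return cls(mat)


def _spectral_noise(n: int, fs: float, shaper, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with amplitude spectrum shaped by ``shaper(f)``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = shaper(freqs[1:])
    spec = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, fs: float, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f**exponent (power) aperiodic background."""
    return _spectral_noise(n, fs, lambda f: f ** (-exponent / 2.0), rng)


def narrowband_noise(n: int, fs: float, center: float, width: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance oscillation: noise with a Gaussian spectral peak."""
    return _spectral_noise(
        n, fs, lambda f: np.exp(-0.5 * ((f - center) / width) ** 2), rng)


def generate_eeg_cohort(latent: LatentArousal, montage: Montage,
                        coupling: CouplingSpec,
                        aperiodic_exponent: float = 1.5,
                        seed: int = 0, fs: float = 200.0,
                        iaf_range: tuple[float, float] = (8.5, 12.5),
                        band_amplitudes: dict[str, float] | None = None,
                        noise_scale: float = 3.0,
                        envelope_noise: float = 1.5,
                        envelope_noise_smoothness_s: float = 40.0,
                        envelope_floor: float = 0.05,
                        carrier: str = "narrowband_noise",
                        n_subjects: int | None = None,
                        scale_uv: float = 10.0) -> list[EegRecording]:
    """Multichannel EEG whose band envelopes follow the latent trajectory.

    Each channel is ``noise_scale`` units of 1/f**chi background plus, per
    band, an oscillation whose amplitude envelope is
    ``1 + beta[ch, band] * latent + envelope_noise * eta`` sampled-and-held
    at 1 s resolution, where eta is an independent slow fluctuation per
    channel and band.  The endogenous term makes the latent explain only a
    modest share of envelope variance, as in real recordings, so coupled
    channels show subject-level correlations of realistic magnitude
    rather than near-perfect tracking.  The envelope is floored at a
    small positive value; a warning is emitted only when the coupling
    itself (``1 + beta * latent``) would go below the floor, i.e. when
    |beta| is unreasonably large.  Oscillations are narrowband-filtered noise
    by default; ``carrier="sine"`` gives deterministic-phase sinusoids for
    exact power bookkeeping.  The per-subject individual alpha frequency
    is drawn uniformly from ``iaf_range`` and stored in recording meta,
    along with the ground-truth envelopes.
    """
    if coupling.beta.shape[0] != montage.n_channels:
        raise ValueError("coupling rows must match montage channel count")
    if band_amplitudes is None:
        band_amplitudes = {"delta": 0.8, "theta": 0.8, "alpha": 1.0}
    if n_subjects is None:
        n_subjects = 12
    n = int(round(latent.duration_s * fs))
    held = latent.sample_and_hold(fs)

    children = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort = []
    for ss in children:
        rng = np.random.default_rng(ss)
        iaf = float(rng.uniform(*iaf_range))
        data = np.empty((montage.n_channels, n))
        env_1hz = np.empty((montage.n_channels, len(BAND_NAMES),
                            latent.duration_s))
        clipped = False
        for c in range(montage.n_channels):
            x = noise_scale * pink_noise(n, fs, aperiodic_exponent, rng)
            for b, band in enumerate(BAND_NAMES):
                center, width = BAND_SHAPE[band]
                if center is None:
                    center = iaf
                driven = 1.0 + coupling.beta[c, b] * held
                if np.any(driven < envelope_floor):
                    clipped = True
                    driven = np.maximum(driven, envelope_floor)
                env = driven
                if envelope_noise > 0:
                    eta = _smooth_gaussian_noise(
                        latent.duration_s, envelope_noise_smoothness_s,
                        fs=1.0, rng=rng)
                    # lognormal (mean-one) endogenous fluctuation: EEG
                    # band power is roughly lognormal, and this keeps the
                    # envelope positive without clipping
                    env = driven * np.exp(
                        envelope_noise * np.repeat(eta, int(round(fs)))
                        - envelope_noise ** 2 / 2.0)
                env_1hz[c, b] = env[::int(round(fs))]
                if band_amplitudes.get(band, 0.0) == 0.0:
                    continue
                if carrier == "sine":
                    phase = rng.uniform(0, 2 * np.pi)
                    osc = np.sqrt(2.0) * np.sin(
                        2 * np.pi * center * np.arange(n) / fs + phase)
                else:
                    osc = narrowband_noise(n, fs, center, width, rng)
                x = x + band_amplitudes[band] * env * osc
            data[c] = scale_uv * x
        if clipped:
            warnings.warn("coupling drove an envelope negative; clipped at "
                          f"floor {envelope_floor}", RuntimeWarning)
        cohort.append(EegRecording(
            data, fs, montage,
            meta={"iaf": iaf, "envelopes_1hz": env_1hz,
                  "bands": BAND_NAMES, "exponent": aperiodic_exponent}))
    return cohort


def generate_resting_eeg(montage: Montage, iafs, duration_s: int = 120,
                         aperiodic_exponent: float = 1.5, seed: int = 0,
                         fs: float = 200.0, alpha_amplitude: float = 4.0,
                         noise_scale: float = 1.0,
                         scale_uv: float = 10.0) -> list[EegRecording]:
    """Eyes-open resting EEG: 1/f background plus a steady alpha rhythm.

    ``iafs`` fixes each subject's alpha peak frequency so rest and movie
    recordings of the same subject share an individual alpha frequency.
    The resting alpha amplitude default is set so that mean resting
    alpha power exceeds mean movie alpha power (visual engagement
    suppresses posterior alpha) even though the movie cohort's lognormal
    envelope fluctuations inflate its mean band power by exp(sigma^2);
    the rest-vs-movie spectral contrast is built to detect exactly this
    decrease.
    """
    n = int(round(duration_s * fs))
    children = np.random.SeedSequence(seed).spawn(len(iafs))
    out = []
    for iaf, ss in zip(iafs, children):
        rng = np.random.default_rng(ss)
        data = np.empty((montage.n_channels, n))
        for c in range(montage.n_channels):
            x = noise_scale * pink_noise(n, fs, aperiodic_exponent, rng)
            x += alpha_amplitude * narrowband_noise(n, fs, float(iaf), 0.5, rng)
            data[c] = scale_uv * x
        out.append(EegRecording(data, fs, montage,
                                meta={"iaf": float(iaf),
                                      "exponent": aperiodic_exponent}))
    return out
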