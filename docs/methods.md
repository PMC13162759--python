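# Methods

This note documents the models, defaults and numerical choices behind
`narousal`, and what the synthetic cohort does and does not emulate.

## The analysis model

The core object of study is the relationship between a shared arousal
trajectory a(t) (1 Hz, z-scored) and per-subject, per-channel EEG band
power. The statistic is

    r_c = (z_c · z_a) / (N − 1)

where z_c is the z-scored, 40 s-smoothed, log₁₀ band-power envelope of
channel c and z_a the z-scored arousal vector. Both standardizations
use the sample SD (ddof = 1), which makes r_c *exactly* the Pearson
correlation coefficient; the test suite asserts the identity to 1e-12.
Group inference treats each subject's channel map r as one observation:
one-sample t per channel, clusters of adjacent same-sign supra-threshold
channels (two-tailed uncorrected α = 0.05, df = N−1), cluster mass Σ|t|,
and a max-mass null from random whole-map sign flips per subject —
valid under the symmetric zero-mean null hypothesis that power is
unrelated to arousal. Mass is unsigned and the null maximum is taken
over both signs, so one null distribution serves both tails; empirical
p-values carry the add-one correction, so p ≥ 1/(n_perm+1).

## Spectral parametrization

Spectra are modelled in log₁₀ power as S(f) = L(f) + Σ Gₙ(f) with
L(f) = b − χ·log₁₀ f (fixed mode — no knee) and Gaussian peaks
(center, height, width). Fitting is sequential then simultaneous:

1. peak-resistant line fit: OLS of log-power on log-frequency, refit
   after dropping bins more than 1 SD *above* the first line (peaks
   only add power, so only upward outliers are peak-contaminated);
2. greedy peak extraction: repeatedly fit a Gaussian at the largest
   residual (width seeded from the half-height span, SD bounded by
   half the width limits 1–20 Hz) until 6 peaks or height < 0.15;
3. aperiodic refit on the peak-subtracted spectrum;
4. one simultaneous least-squares refinement of all parameters,
   falling back to the sequential estimates if it fails to converge.

The flattened spectrum is S − L on the fitted range. The IAF is the
frequency of maximal flattened power within 8–13 Hz, required to be
backed by a fitted peak in that range (otherwise `NoAlphaPeakError`
tells the caller to fall back to the group-median IAF, as the pipeline
driver does); it is estimated on 0.1 Hz-resolution spectra (2 s Hann
windows zero-padded to 10 s) over 1–40 Hz, while the general fit uses
2–40 Hz. Recovery, measured by the acceptance script: aperiodic
exponent mean absolute error ≈ 0.03 over χ ∈ {0.5, 1, 1.5, 2} from
Welch spectra of pure 1/f^χ noise (120 s at 200 Hz), peak centers and
IAF exact to the grid on constructed spectra.

## Pupil pipeline choices

"Large spikes" are unquantified in standard descriptions of this
pipeline, so a sample is a spike when it deviates from the 100-point
running median by more than 5 MAD. Both the spike MAD and the de-blink
derivative SD are floored at 2 % of the trace's overall robust scale
(MAD about the global median): on an already-cleaned, very smooth trace
the residual scale collapses toward zero and an unfloored threshold
would flag benign curvature — the floor is what makes re-cleaning a
cleaned trace approximately a no-op while leaving blink edges (tens of
robust scales) untouched. The derivative threshold is computed once,
after the first interpolation pass, two-sided. Median filters use
reflected-edge padding. The missingness gate fires iff the missing
fraction exceeds 0.40 at any stage, raising `SubjectExcluded` with the
stage name. The 1 Hz grid spans seconds 0 … duration−1; the cleaned
trace (which starts 300 samples = 5 s into the movie) is linearly
interpolated with nearest-value extrapolation at the ends. Luminance
regression precedes Gaussian smoothing; residuals are orthogonal to
luminance to machine precision by construction.

The Gaussian smoothing kernel shared by the pupil and band-power
pipelines spans a 40-sample window with σ = window/6, realized with an
odd tap count (41) so the impulse response is exactly centered, and
renormalized at the edges so constants map to themselves.

## The synthetic cohort

The generator defines the study conditions; its defaults are fixed
once and shared by the pipeline, tests and acceptance script.

* **Latent arousal**: low-pass-filtered Gaussian noise (4th-order
  Butterworth, cutoff 1/smoothness, default smoothness 40 s), z-scored.
  No published generative model for arousal dynamics exists at this
  granularity; a controllable autocorrelation matching the pipeline's
  40 s smoothing scale is the design requirement.
* **Annotation raters**: fidelity-weighted mixtures
  f·latent + (1−f)·independent smooth noise, affinely mapped to the
  0–250 rating scale (center 125, gain 45) and clipped. The expected
  pairwise correlation is f²/(f² + (1−f)²); the demo configuration
  uses f = 0.5 so cohort ISC lands in the ≈0.5 regime typical of
  engaged audiences.
* **Pupil**: baseline 4.0 + 0.3·latent − 0.004·luminance + noise at
  60 Hz, with white measurement noise (SD 0.05), slow idiosyncratic
  arousal (SD 0.25, same timescale as the latent — this keeps pupil
  ISC below 1, as in real cohorts), blinks at 10/min (200–400 ms drops
  to 3 % of baseline with 50 ms ramps strictly below baseline), spikes
  at 2/min and dropouts at 0.5/min. Luminance itself is smooth bounded
  grey-level noise (mean 110, SD 35, 8 s timescale).
* **EEG**: per channel, `noise_scale` (default 3) units of 1/f^χ
  background (default χ = 1.5) plus, per band, an oscillation realized
  as narrowband-filtered noise (Gaussian spectral peaks at 2.5, 5.5 and
  the subject's IAF, drawn uniformly from 8.5–12.5 Hz) — pure tones
  would make Welch power estimates degenerate, but a `carrier="sine"`
  mode exists for exact power bookkeeping in tests. The amplitude
  envelope is (1 + β·latent)·exp(σ·η − σ²/2), sampled-and-held at 1 s:
  β is the ground-truth coupling (posterior channels, −0.3 by default)
  and η an independent slow fluctuation per channel and band
  (σ = 1.5, 40 s timescale). The lognormal endogenous term is the
  realism knob: EEG band power is approximately lognormal and mostly
  endogenous, so arousal should explain only a modest share of
  envelope variance. With the defaults, coupled channels show
  subject-level correlations of ≈ −0.2 — the realistic regime —
  instead of the ≈ −0.95 that a noise-free envelope would give.
  Resting recordings share each subject's IAF with a constant-envelope
  alpha rhythm whose amplitude (4.0) exceeds the movie cohort's mean
  alpha (inflated exp(σ²)-fold by the envelope noise), so the
  rest-vs-movie contrast detects the posterior alpha suppression that
  visual engagement produces.

What the generator does **not** emulate: volume conduction or any
head-geometry mixing between channels, ocular/muscle/line artifacts in
the EEG, rater reaction-time lag relative to the stimulus, or
non-stationary artifact statistics. Passing tests therefore demonstrate
that the statistics recover couplings of realistic magnitude under
realistic noise *structure*, not that the pipeline is robust to every
failure mode of real recordings.

## Problem sizes and calibration experiments

All simulation experiments run at desk scale, chosen once:

* Demo pipeline: 12 subjects per modality, 32 channels, 600 s movie,
  120 s rest, 200 Hz; permutations: 1000 (ISC), 2000 (spatial
  clusters), 1000 (frequency clusters). Full-study scale (25 subjects,
  64 channels, 1200 s, 10 000 permutations) is a `PipelineConfig` away.
* Coupling recovery: 100 replicate cohorts of 12 subjects × 16
  channels (8 posterior coupled) × 300 s, n_perm = 1000. Detection is
  a significant negative cluster touching a coupled channel; the
  false-cluster rate counts significant clusters wholly within
  uncoupled channels and stays at the nominal FWER.
* Type-I calibration: 300 null cohorts (8 independent smooth series,
  300 s) for the circular-shift ISC test; 1000 null map sets
  (12 × 32 iid Gaussian) for the sign-flip cluster test, which is
  cheap enough that the larger replicate count and correspondingly
  tighter binomial interval cost only seconds.

Degenerate inputs are handled explicitly rather than propagated:
constant series are rejected by name (ISC, z-scoring), |r| = 1 is
clipped to 1 − 1e-12 with a warning before Fisher z, zero-variance
paired differences raise instead of emitting infinite t, epoched power
is floored at 1e-20 before log₁₀, and envelope clipping at 0.05 warns
only when the deterministic coupling term itself would go negative.
Connected-component labeling iterates channels in index order, so
cluster enumeration is deterministic; permutation draws come from
`numpy.random.default_rng` seeded explicitly at every call site.

At 32-channel density the 0.4 adjacency threshold leaves some outer
frontal electrodes without neighbours (the threshold is natural for a
64-channel cap); singleton clusters remain admissible, and the
parieto-occipital region — where the simulated couplings live — forms
a single connected component.

## Known limitations

* The spectral decomposition is this package's own implementation of
  the aperiodic-plus-peaks model; it matches the published settings
  (fixed mode, ≤6 peaks, width limits 1–20 Hz, min height 0.15) but is
  not guaranteed to reproduce other implementations bin-for-bin.
* The circular-shift test assumes approximate stationarity; for series
  whose correlation time approaches the recording length, the
  surrogate null degrades (the calibration experiment uses a 10 s
  timescale over 300 s, where it is exact to binomial precision).
* Cross-modal agreement between annotation and pupil group means is
  higher in the synthetic cohort (r ≈ 0.9) than in real cohorts
  (≈ 0.4): both modalities inherit the same latent with only additive
  noise, whereas real subjective reports and autonomic signals share
  only part of their generative process.
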