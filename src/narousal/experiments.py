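"""Reusable simulation experiments: calibration, recovery, identities.

These drivers define the study conditions once, so the test suite, the
acceptance script and the analysis scripts all measure the same thing:

* type-I calibration of the two permutation engines (circular-shift ISC
  and spatial sign-flip clustering) on null cohorts;
* recovery of known arousal-to-band-power couplings through the full
  EEG pipeline (generate -> epoch -> transform -> correlate -> cluster);
* recovery of aperiodic exponents, peak centers and the individual
  alpha frequency from synthetic spectra;
* the dot-product / Pearson identity and the pupil-pipeline guarantees.

Problem sizes are chosen for desk-scale runtimes and are stated in
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import bandpower, clusterstats, isc, pupil, spectral, synthetic
from .montage import POSTERIOR_32, Montage, standard_montage
from .synthetic import CouplingSpec, generate_latent_arousal
from .trajectories import ArousalTrajectory, group_mean_trajectory

#: 16-channel layout for the coupling-recovery experiment: a frontal
#: octet (uncoupled) and the posterior octet that carries the coupling.
RECOVERY_FRONTAL = ["Fp1", "Fp2", "F3", "Fz", "F4", "FC1", "FCz", "FC2"]
RECOVERY_POSTERIOR = list(POSTERIOR_32)
RECOVERY_CHANNELS = RECOVERY_FRONTAL + RECOVERY_POSTERIOR


# ---------------------------------------------------------------------------
# permutation-engine calibration
# ---------------------------------------------------------------------------

def isc_type1_calibration(n_reps: int = 300, n_subjects: int = 8,
                          duration_s: int = 300, smoothness_s: float = 10.0,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> dict:
    """Rejection rate of the circular-shift ISC test on null cohorts.

    Each replicate is a cohort of mutually independent smooth
    (autocorrelated) series — exactly the structure the surrogate test
    must respect.  Under the null the rejection rate at ``alpha`` should
    sit inside the binomial interval around ``alpha``.
    """
    root = np.random.SeedSequence(seed)
    rejections = 0
    pvals = np.empty(n_reps)
    for rep, ss in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(ss)
        series = np.stack([
            synthetic._smooth_gaussian_noise(duration_s, smoothness_s, 1.0, rng)
            for _ in range(n_subjects)])
        perm_seed = int(rng.integers(2**31))
        res = isc.circular_shift_null(series, n_perm=n_perm,
                                      min_shift_s=10.0, seed=perm_seed)
        pvals[rep] = res.p
        rejections += res.p < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps,
            "alpha": alpha, "pvals": pvals}


def cluster_type1_calibration(n_reps: int = 300, n_subjects: int = 12,
                              n_perm: int = 1000, alpha: float = 0.05,
                              seed: int = 0,
                              montage: Montage | None = None) -> dict:
    """Family-wise rejection rate of the sign-flip cluster test on noise.

    Null maps are iid Gaussian (subjects x channels); a replicate counts
    as a rejection if any cluster reaches corrected p < alpha.
    """
    if montage is None:
        montage = standard_montage()
    adjacency = clusterstats.build_adjacency(montage)
    root = np.random.SeedSequence(seed)
    rejections = 0
    for ss in root.spawn(n_reps):
        rng = np.random.default_rng(ss)
        maps = rng.standard_normal((n_subjects, montage.n_channels))
        clusters = clusterstats.signflip_permutation(
            maps, adjacency, n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(2**31)))
        if any(cl.p_corrected < alpha for cl in clusters):
            rejections += 1
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def binomial_interval(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% interval for a binomial rate."""
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


# ---------------------------------------------------------------------------
# coupling recovery through the full EEG pipeline
# ---------------------------------------------------------------------------

def _subject_correlation_maps(recording, trajectory: ArousalTrajectory,
                              bands) -> dict[str, np.ndarray]:
    """Per-band channel correlation map for one subject."""
    powers = bandpower.epoch_band_power(recording, bands)
    out = {}
    for name, series in powers.items():
        z = bandpower.transform_power(series)
        out[name] = bandpower.correlate_with_arousal(z, trajectory)
    return out


def run_coupling_pipeline(latent, montage: Montage, coupling: CouplingSpec,
                          trajectory: ArousalTrajectory, seed: int,
                          n_subjects: int = 12,
                          noise_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Generate a coupled EEG cohort and return per-band map stacks.

    Band power uses each subject's ground-truth IAF (the recovery
    question is about the coupling, not IAF detection, which has its own
    experiment).  Returns {band: (n_subjects, n_channels) array} with the
    analysis band names mapped onto the generator's (alpha -> low_iaf).
    """
    cohort = synthetic.generate_eeg_cohort(
        latent, montage, coupling, seed=seed, n_subjects=n_subjects,
        noise_scale=noise_scale)
    maps: dict[str, list[np.ndarray]] = {}
    for rec in cohort:
        bands = bandpower.correlation_bands(rec.meta["iaf"])
        sub = _subject_correlation_maps(rec, trajectory, bands)
        for name, r in sub.items():
            maps.setdefault(name, []).append(r)
    return {name: np.stack(rows) for name, rows in maps.items()}


def coupling_recovery(n_reps: int = 100, n_subjects: int = 12,
                      duration_s: int = 300, beta: float = -0.3,
                      n_perm: int = 1000, alpha: float = 0.05,
                      seed: int = 0, rater_fidelity: float = 0.8,
                      n_raters: int = 12) -> dict:
    """Power and specificity of the end-to-end coupling analysis.

    Every replicate builds a fresh cohort with negative posterior
    coupling in all three bands, correlates each subject's band power
    with the group-mean annotation trajectory, and runs the sign-flip
    cluster test.  Reported per band:

    * ``detection_rate`` — replicates with a significant negative
      cluster containing at least one coupled (posterior) channel;
    * ``false_cluster_rate`` — replicates with a significant cluster
      made entirely of uncoupled (frontal) channels;
    * ``mean_coupled_r`` — subject-level correlation in coupled
      channels, averaged over subjects, channels and replicates.
    """
    montage = standard_montage(RECOVERY_CHANNELS)
    coupled_idx = set(montage.index(RECOVERY_POSTERIOR).tolist())
    coupling = CouplingSpec.posterior(montage, RECOVERY_POSTERIOR, beta=beta)
    adjacency = clusterstats.build_adjacency(montage)

    root = np.random.SeedSequence(seed)
    bands = ("delta", "theta", "low_iaf")
    hits = {b: 0 for b in bands}
    false = {b: 0 for b in bands}
    coupled_r = {b: [] for b in bands}
    for ss in root.spawn(n_reps):
        rng = np.random.default_rng(ss)
        s_lat, s_ann, s_eeg, s_perm = (int(v) for v in
                                       rng.integers(2**31, size=4))
        latent = generate_latent_arousal(duration_s, seed=s_lat)
        raters = synthetic.generate_annotation_cohort(
            latent, n_raters, rater_fidelity, seed=s_ann)
        traj = group_mean_trajectory(raters)
        maps = run_coupling_pipeline(latent, montage, coupling, traj,
                                     seed=s_eeg, n_subjects=n_subjects)
        for band in bands:
            clusters = clusterstats.signflip_permutation(
                maps[band], adjacency, n_perm=n_perm, alpha=alpha,
                seed=s_perm)
            sig = [c for c in clusters if c.p_corrected < alpha]
            if any(c.sign < 0 and (set(c.members.tolist()) & coupled_idx)
                   for c in sig):
                hits[band] += 1
            if any(not (set(c.members.tolist()) & coupled_idx)
                   for c in sig):
                false[band] += 1
            coupled_r[band].append(
                maps[band][:, sorted(coupled_idx)].mean())
    return {
        "detection_rate": {b: hits[b] / n_reps for b in bands},
        "false_cluster_rate": {b: false[b] / n_reps for b in bands},
        "mean_coupled_r": {b: float(np.mean(coupled_r[b])) for b in bands},
        "n_reps": n_reps, "beta": beta,
    }


# ---------------------------------------------------------------------------
# spectral recovery
# ---------------------------------------------------------------------------

def exponent_recovery(chis=(0.5, 1.0, 1.5, 2.0), duration_s: int = 120,
                      fs: float = 200.0, seed: int = 0) -> dict:
    """Fit error of the aperiodic exponent on pure 1/f**chi noise."""
    errors = []
    root = np.random.SeedSequence(seed)
    for chi, ss in zip(chis, root.spawn(len(chis))):
        rng = np.random.default_rng(ss)
        x = synthetic.pink_noise(int(duration_s * fs), fs, chi, rng)
        spec = spectral.welch_psd(x, fs)
        fit = spectral.fit_spectral_model(spec)
        errors.append(abs(fit.aperiodic.exponent - chi))
    return {"chis": list(chis), "errors": errors,
            "mae": float(np.mean(errors))}


def synthetic_spectrum(freqs: np.ndarray, offset: float, exponent: float,
                       peaks=()) -> spectral.PowerSpectrum:
    """An exact model spectrum (line plus Gaussians) on a given grid."""
    y = offset - exponent * np.log10(freqs)
    for c, h, w in peaks:
        y = y + h * np.exp(-0.5 * ((freqs - c) / w) ** 2)
    return spectral.PowerSpectrum(freqs, y,
                                  resolution=float(freqs[1] - freqs[0]))


def peak_center_recovery(centers=(4.0, 6.0, 10.0, 13.0, 16.0),
                         height: float = 0.5, width: float = 1.5,
                         exponent: float = 1.0) -> dict:
    """Center error on constructed one-peak spectra over a center grid."""
    freqs = np.arange(1.0, 40.05, 0.25)
    errors = []
    for c in centers:
        spec = synthetic_spectrum(freqs, 1.0, exponent,
                                  peaks=[(c, height, width)])
        fit = spectral.fit_spectral_model(spec)
        if not fit.peaks:
            errors.append(np.inf)
            continue
        best = min(fit.peaks, key=lambda pk: abs(pk.center - c))
        errors.append(abs(best.center - c))
    return {"centers": list(centers), "errors": errors,
            "mae": float(np.mean(errors))}


def iaf_recovery(alphas=(8.5, 9.7, 10.3, 11.6, 12.4)) -> dict:
    """IAF error on constructed high-resolution (0.1 Hz) spectra."""
    freqs = np.arange(1.0, 40.05, 0.1)
    errors = []
    for a in alphas:
        spec = synthetic_spectrum(freqs, 1.0, 1.2,
                                  peaks=[(a, 0.6, 1.2), (20.0, 0.2, 2.0)])
        est = spectral.estimate_iaf(spec)
        errors.append(abs(est.iaf - a))
    return {"alphas": list(alphas), "errors": errors,
            "max_error": float(np.max(errors))}


# ---------------------------------------------------------------------------
# identities and pupil-pipeline guarantees
# ---------------------------------------------------------------------------

def pearson_identity_check(n_pairs: int = 1000, n: int = 500,
                           seed: int = 0) -> float:
    """Max |dot-product statistic - Pearson r| over random vector pairs."""
    from scipy import stats
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        dp = bandpower.dot_product_correlation(x, y)
        r = stats.pearsonr(x, y).statistic
        worst = max(worst, abs(dp - r))
    return worst


def pupil_pipeline_checks(duration_s: int = 600, n_subjects: int = 5,
                          seed: int = 0) -> dict:
    """Blink detection, luminance orthogonality and the missingness gate.

    Returns the blink-sample detection fraction across a cohort with
    injected artifacts, the worst |corr(residual, luminance)| after OLS
    removal, and whether the >40% gate fires exactly when constructed to.
    """
    latent = generate_latent_arousal(duration_s, seed=seed)
    lum = synthetic.generate_luminance(duration_s, seed=seed + 1)
    cohort = synthetic.generate_pupil_cohort(latent, lum, n_subjects,
                                             seed=seed + 2)
    detected = 0
    total = 0
    worst_orth = 0.0
    for sim in cohort:
        qc: dict = {}
        cleaned = pupil.clean_pupil(sim.raw, qc=qc)
        blink = sim.blink_mask[pupil.N_INITIAL_DROP:]
        flagged = qc["repaired_mask"]
        detected += int((blink & flagged).sum())
        total += int(blink.sum())
        grid = np.arange(int(lum.duration_s), dtype=float)
        t = pupil.N_INITIAL_DROP / sim.raw.fs + cleaned.times()
        on_grid = np.interp(grid, t, cleaned.values)
        resid, _, _ = pupil.regress_out(on_grid, lum.values)
        worst_orth = max(worst_orth,
                         abs(np.corrcoef(resid, lum.values)[0, 1]))

    # gate construction: a run of exactly 50% missing must exclude,
    # 30% must pass
    n = duration_s * 60
    base = cohort[0].clean.values.copy()
    fired = {}
    for frac in (0.50, 0.30):
        mask = np.zeros(n, dtype=bool)
        start = pupil.N_INITIAL_DROP
        width = int((n - start) * frac) + 1
        mask[start:start + width] = True
        trace = synthetic.TimeSeries1D(base.copy(), 60.0, mask)
        try:
            pupil.clean_pupil(trace)
            fired[frac] = False
        except pupil.SubjectExcluded:
            fired[frac] = True
    return {
        "blink_detection_rate": detected / total if total else float("nan"),
        "max_abs_residual_luminance_corr": worst_orth,
        "gate_fired_at_50pct": fired[0.50],
        "gate_fired_at_30pct": fired[0.30],
    }
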