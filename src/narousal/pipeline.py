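"""End-to-end driver: simulate -> preprocess -> correlate -> cluster.

Runs the whole analysis on a synthetic cohort and writes a report bundle
(JSON/CSV) mirroring the structure of a sensor-level results table:
quality control for the pupil pipeline, ISC of annotations and pupil,
the rest-vs-movie spectral contrast, and per-band cluster tables for the
power-arousal correlations, alongside a ground-truth-vs-recovered
coupling summary.  Fully deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bandpower, clusterstats, isc, pupil, spectral, synthetic
from .montage import OCCIPITAL, POSTERIOR_32, standard_montage
from .trajectories import crossmodal_correlation, group_mean_trajectory

log = logging.getLogger("narousal")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through JSON unchanged."""

    seed: int = 0
    duration_s: int = 600
    n_annotation_subjects: int = 12
    n_pupil_subjects: int = 12
    n_eeg_subjects: int = 12
    channels: list[str] = field(default_factory=lambda: None)  # type: ignore
    coupled_channels: list[str] = field(
        default_factory=lambda: list(POSTERIOR_32))
    beta: float = -0.3
    annotation_fidelity: float = 0.5
    rest_duration_s: int = 120
    contrast_window_s: int = 120
    smooth_window_s: int = 40
    n_perm_isc: int = 1000
    n_perm_cluster: int = 2000
    n_perm_spectral: int = 1000
    adjacency_threshold: float = 0.4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.channels is None:
            from .montage import CHANNELS_32
            self.channels = list(CHANNELS_32)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _cluster_table(clusters, labels, maps, n_subjects, band, measure):
    rows = []
    for cl in clusters:
        avg_r = float(maps[:, cl.members].mean())
        rows.append({
            "band": band, "measure": measure,
            "channels": " ".join(labels[i] for i in cl.members),
            "n_channels": cl.n_members,
            "cluster_mass": cl.signed_mass, "p": cl.p_corrected,
            "peak_t": cl.peak_t,
            "cohens_d": clusterstats.cohens_d_from_t(cl.peak_t, n_subjects),
            "avg_r": avg_r,
            "significant": cl.p_corrected < 0.05,
        })
    return rows


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns the report as a dict (the JSON artifacts' in-memory form).
    Any stage failure propagates with the stage logged; artifacts written
    before the failure are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    cfg.save(outdir / "config.json")
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(s) for name, s in zip(
        ["latent", "luminance", "annotations", "pupil", "eeg", "rest",
         "isc_annot", "isc_pupil", "cluster", "spectral"],
        rng.integers(2**31, size=10))}
    log.info("stage seeds: %s", seeds)
    report: dict = {"seeds": seeds}

    # --- simulate ----------------------------------------------------------
    log.info("stage: simulate")
    latent = synthetic.generate_latent_arousal(cfg.duration_s,
                                               seed=seeds["latent"])
    lum = synthetic.generate_luminance(cfg.duration_s, seed=seeds["luminance"])
    annots = synthetic.generate_annotation_cohort(
        latent, cfg.n_annotation_subjects, cfg.annotation_fidelity,
        seed=seeds["annotations"])
    pupils = synthetic.generate_pupil_cohort(
        latent, lum, cfg.n_pupil_subjects, seed=seeds["pupil"])
    montage = standard_montage(cfg.channels)
    coupling = synthetic.CouplingSpec.posterior(
        montage, cfg.coupled_channels, beta=cfg.beta)
    movie_eeg = synthetic.generate_eeg_cohort(
        latent, montage, coupling, seed=seeds["eeg"],
        n_subjects=cfg.n_eeg_subjects)
    rest_eeg = synthetic.generate_resting_eeg(
        montage, [rec.meta["iaf"] for rec in movie_eeg],
        duration_s=cfg.rest_duration_s, seed=seeds["rest"])

    # --- pupil preprocessing -----------------------------------------------
    log.info("stage: pupil preprocessing")
    qc_all = []
    pupil_1hz = []
    for i, sim in enumerate(pupils):
        qc: dict = {}
        try:
            cleaned = pupil.clean_pupil(sim.raw, qc=qc)
        except pupil.SubjectExcluded as exc:
            qc_all.append({"subject": i, "excluded": True,
                           "stage": exc.stage, "fraction": exc.fraction})
            continue
        traj = pupil.resample_and_regress(cleaned, lum,
                                          smooth_window_s=cfg.smooth_window_s,
                                          report=qc)
        pupil_1hz.append(traj)
        qc_all.append({"subject": i, "excluded": False,
                       "missing_fraction": qc["missing_fraction"],
                       "luminance_slope": qc["luminance_slope"]})
    (outdir / "pupil_qc.json").write_text(json.dumps(qc_all, indent=2))
    report["pupil_qc"] = qc_all

    # --- trajectories and ISC ----------------------------------------------
    log.info("stage: trajectories / ISC")
    annot_traj = group_mean_trajectory(annots, modality="annotation")
    pupil_traj = group_mean_trajectory(pupil_1hz, modality="pupil")
    r_xm, p_xm = crossmodal_correlation(annot_traj, pupil_traj)
    annot_isc = isc.circular_shift_null(
        np.stack([s.values for s in annots]), n_perm=cfg.n_perm_isc,
        seed=seeds["isc_annot"])
    pupil_isc = isc.circular_shift_null(
        np.stack([s.values for s in pupil_1hz]), n_perm=cfg.n_perm_isc,
        seed=seeds["isc_pupil"])
    report["isc"] = {
        "annotations": {"mean_r": annot_isc.mean_r, "sd_r": annot_isc.sd_r,
                        "p": annot_isc.p, "n": annot_isc.n_subjects},
        "pupil": {"mean_r": pupil_isc.mean_r, "sd_r": pupil_isc.sd_r,
                  "p": pupil_isc.p, "n": pupil_isc.n_subjects},
        "crossmodal_r": r_xm, "crossmodal_p": p_xm,
    }
    (outdir / "isc.json").write_text(json.dumps(report["isc"], indent=2))

    # --- spectral contrast ---------------------------------------------------
    log.info("stage: spectral contrast")
    occ = [ch for ch in OCCIPITAL if ch in montage.labels]
    occ_idx = montage.index(occ)
    n_contrast = int(cfg.contrast_window_s * movie_eeg[0].fs)
    exps_rest, exps_movie, iafs = [], [], []
    flat_rest, flat_movie, flat_freqs = [], [], None
    for rest, movie in zip(rest_eeg, movie_eeg):
        spec_rest = spectral.welch_psd(rest.data, rest.fs)
        spec_movie = spectral.welch_psd(movie.data[:, :n_contrast], movie.fs)
        exps_rest.append(
            spectral.fit_spectral_model(spec_rest).aperiodic.exponent)
        exps_movie.append(
            spectral.fit_spectral_model(spec_movie).aperiodic.exponent)
        hi_res = spectral.welch_psd(rest.data, rest.fs, window_s=2.0,
                                    zero_pad_s=10.0)
        try:
            iafs.append(spectral.estimate_iaf(hi_res).iaf)
        except spectral.NoAlphaPeakError:
            iafs.append(None)
        fr = spectral.fit_spectral_model(
            spectral.welch_psd(rest.data[occ_idx], rest.fs))
        fm = spectral.fit_spectral_model(
            spectral.welch_psd(movie.data[occ_idx, :n_contrast], movie.fs))
        flat_rest.append(fr.flattened.power)
        flat_movie.append(fm.flattened.power)
        flat_freqs = fr.flattened.freqs
    median_iaf = float(np.median([v for v in iafs if v is not None]))
    iafs = [v if v is not None else median_iaf for v in iafs]
    contrast = spectral.aperiodic_contrast(exps_rest, exps_movie)
    freq_clusters = spectral.frequency_cluster_test(
        np.stack(flat_rest), np.stack(flat_movie), flat_freqs,
        n_perm=cfg.n_perm_spectral, seed=seeds["spectral"])
    report["spectral"] = {
        "aperiodic_contrast": {"t": contrast.t, "df": contrast.df,
                               "p": contrast.p,
                               "mean_rest": contrast.mean_a,
                               "mean_movie": contrast.mean_b},
        "iaf": iafs,
        "occipital_clusters": [
            {"freq_range": cl.freq_range, "sign": cl.sign,
             "mass": cl.signed_mass, "p": cl.p_corrected}
            for cl in freq_clusters],
    }
    (outdir / "spectral.json").write_text(
        json.dumps(report["spectral"], indent=2))

    # --- band power and cluster statistics ---------------------------------
    log.info("stage: band power / cluster statistics")
    adjacency = clusterstats.build_adjacency(montage,
                                             cfg.adjacency_threshold)
    maps: dict[tuple[str, str], list[np.ndarray]] = {}
    for rec, iaf in zip(movie_eeg, iafs):
        powers = bandpower.epoch_band_power(
            rec, bandpower.correlation_bands(iaf))
        for name, series in powers.items():
            z = bandpower.transform_power(
                series, smooth_window_s=cfg.smooth_window_s)
            for measure, traj in (("annotations", annot_traj),
                                  ("pupil", pupil_traj)):
                maps.setdefault((name, measure), []).append(
                    bandpower.correlate_with_arousal(z, traj))
    table_rows = []
    for (band, measure), rows in maps.items():
        stack = np.stack(rows)
        clusters = clusterstats.signflip_permutation(
            stack, adjacency, n_perm=cfg.n_perm_cluster,
            alpha=cfg.alpha, seed=seeds["cluster"])
        table_rows += _cluster_table(clusters, montage.labels, stack,
                                     stack.shape[0], band, measure)
    table = pd.DataFrame(table_rows)
    table.to_csv(outdir / "cluster_table.csv", index=False)
    report["cluster_table"] = table_rows

    # --- ground truth vs recovered -----------------------------------------
    coupled_idx = montage.index(cfg.coupled_channels)
    recovery = {}
    for (band, measure), rows in maps.items():
        stack = np.stack(rows)
        recovery[f"{band}/{measure}"] = {
            "mean_r_coupled": float(stack[:, coupled_idx].mean()),
            "mean_r_uncoupled": float(
                np.delete(stack, coupled_idx, axis=1).mean()),
            "true_beta": cfg.beta,
        }
    report["coupling_recovery"] = recovery
    (outdir / "coupling_recovery.json").write_text(
        json.dumps(recovery, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    log.info("pipeline complete: %s", outdir)
    return report
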