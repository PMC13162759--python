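"""Simulate the full synthetic viewing cohort and serialize it.

Writes: annotation and raw-pupil traces plus the luminance series as CSV
under results/analysis/cohort/, EEG (movie + rest) as .npy under
scratch/analysis/, and a manifest recording every seed and the
ground-truth coupling matrix.
"""

import json

import numpy as np

from narousal import synthetic
from narousal.montage import standard_montage

from common import RESULTS, SCRATCH, config


def main() -> None:
    cfg = config()
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort_dir = RESULTS / "cohort"
    cohort_dir.mkdir(exist_ok=True)
    eeg_dir = SCRATCH / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    cfg.save(RESULTS / "config.json")

    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(s) for k, s in zip(
        ["latent", "luminance", "annotations", "pupil", "eeg", "rest"],
        rng.integers(2**31, size=6))}

    latent = synthetic.generate_latent_arousal(cfg.duration_s,
                                               seed=seeds["latent"])
    lum = synthetic.generate_luminance(cfg.duration_s,
                                       seed=seeds["luminance"])
    annots = synthetic.generate_annotation_cohort(
        latent, cfg.n_annotation_subjects, cfg.annotation_fidelity,
        seed=seeds["annotations"])
    pupils = synthetic.generate_pupil_cohort(
        latent, lum, cfg.n_pupil_subjects, seed=seeds["pupil"])
    montage = standard_montage(cfg.channels)
    coupling = synthetic.CouplingSpec.posterior(
        montage, cfg.coupled_channels, beta=cfg.beta)
    movie = synthetic.generate_eeg_cohort(latent, montage, coupling,
                                          seed=seeds["eeg"],
                                          n_subjects=cfg.n_eeg_subjects)
    rest = synthetic.generate_resting_eeg(
        montage, [r.meta["iaf"] for r in movie],
        duration_s=cfg.rest_duration_s, seed=seeds["rest"])

    np.savetxt(cohort_dir / "latent.csv", latent.values, header="value",
               comments="")
    np.savetxt(cohort_dir / "luminance.csv", lum.values, header="value",
               comments="")
    for i, s in enumerate(annots):
        s.to_csv(cohort_dir / f"annotation_{i:02d}.csv")
    for i, sim in enumerate(pupils):
        sim.raw.to_csv(cohort_dir / f"pupil_raw_{i:02d}.csv")
        sim.clean.to_csv(cohort_dir / f"pupil_truth_{i:02d}.csv")
    for i, (m, r) in enumerate(zip(movie, rest)):
        np.save(eeg_dir / f"movie_{i:02d}.npy", m.data)
        np.save(eeg_dir / f"rest_{i:02d}.npy", r.data)
    manifest = {
        "seeds": seeds, "channels": montage.labels,
        "true_iaf": [r.meta["iaf"] for r in movie],
        "beta": coupling.beta.tolist(), "bands": list(coupling.bands),
        "config": cfg.to_dict(),
    }
    (cohort_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"cohort written: {cfg.n_annotation_subjects} raters, "
          f"{cfg.n_pupil_subjects} pupil traces, {cfg.n_eeg_subjects} EEG "
          f"subjects x {montage.n_channels} channels x {cfg.duration_s} s")


if __name__ == "__main__":
    main()
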