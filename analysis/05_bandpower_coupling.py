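"""Time-resolved band power and its correlation with the arousal means.

Per subject and band (delta, theta, low IAF): 1 s epoch log power,
40 s Gaussian smoothing, z-scoring, then the per-channel correlation
with each group-mean arousal trajectory.  Writes the long-format
correlation-map table consumed by the cluster statistics stage.
"""

import json

import numpy as np
import pandas as pd

from narousal import correlation_bands, correlate_with_arousal, \
    epoch_band_power, transform_power
from narousal.montage import EegRecording, standard_montage
from narousal.trajectories import ArousalTrajectory

from common import RESULTS, SCRATCH, config


def main() -> None:
    cfg = config()
    manifest = json.loads((RESULTS / "cohort" / "manifest.json").read_text())
    montage = standard_montage(manifest["channels"])
    iafs = json.loads((RESULTS / "spectral.json").read_text())["iaf"]
    trajs = {
        "annotations": ArousalTrajectory(
            np.loadtxt(RESULTS / "trajectory_annotations.csv", skiprows=1),
            cfg.n_annotation_subjects, "annotation"),
        "pupil": ArousalTrajectory(
            np.loadtxt(RESULTS / "trajectory_pupil.csv", skiprows=1),
            cfg.n_pupil_subjects, "pupil"),
    }
    rows = []
    for i in range(cfg.n_eeg_subjects):
        data = np.load(SCRATCH / "eeg" / f"movie_{i:02d}.npy")
        rec = EegRecording(data, 200.0, montage)
        powers = epoch_band_power(rec, correlation_bands(iafs[i]))
        for band, series in powers.items():
            z = transform_power(series, smooth_window_s=cfg.smooth_window_s)
            for measure, traj in trajs.items():
                r = correlate_with_arousal(z, traj)
                for ch, val in zip(montage.labels, r):
                    rows.append({"subject": i, "band": band,
                                 "measure": measure, "channel": ch,
                                 "r": val})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "correlation_maps.csv", index=False)
    summary = (table.groupby(["band", "measure"])["r"]
               .agg(["mean", "std"]).round(3))
    print("per-channel correlation with arousal (all channels pooled):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
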