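"""Group-level arousal trajectories and the annotation/pupil comparison.

The shared arousal signal of a viewing cohort is estimated by z-scoring
each subject's 1 Hz series and averaging element-wise.  Averaging
suppresses idiosyncratic rater noise, so the group mean tracks the
common (stimulus-driven) trajectory better than any single subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .smoothing import zscore
from .timeseries import TimeSeries1D

ANNOTATION_RANGE = (0.0, 250.0)
ANNOTATION_FS = 1.0


@dataclass
class ArousalTrajectory:
    """Group-mean arousal at 1 Hz (z-scored inputs), with provenance."""

    values: np.ndarray
    n_subjects: int
    modality: str  # "annotation" or "pupil"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")

    def __len__(self) -> int:
        return self.values.size


def validate_annotations(series: TimeSeries1D) -> TimeSeries1D:
    """Check an annotation series is 1 Hz and within the 0-250 scale."""
    if series.fs != ANNOTATION_FS:
        raise ValueError(
            f"annotations must be sampled at 1 Hz, got {series.fs} Hz")
    lo, hi = ANNOTATION_RANGE
    bad = (series.values < lo) | (series.values > hi)
    if np.any(bad[~series.missing_mask]):
        worst = series.values[bad][0]
        raise ValueError(
            f"annotation value {worst} outside the rating scale [{lo}, {hi}]")
    return series


def group_mean_trajectory(series_list, zscore_first: bool = True,
                          modality: str = "annotation") -> ArousalTrajectory:
    """Per-subject z-score (optional) followed by element-wise mean.

    Zero-variance subjects cannot be z-scored; they are dropped with a
    warning naming the subject index rather than poisoning the mean.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 series to form a group mean")
    lengths = {len(s) for s in series_list}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    rows = []
    for i, s in enumerate(series_list):
        v = np.asarray(s.values if isinstance(s, TimeSeries1D) else s,
                       dtype=float)
        if zscore_first:
            if v.std(ddof=1) == 0:
                warnings.warn(f"subject {i} has zero variance; excluded "
                              "from group mean", RuntimeWarning)
                continue
            v = zscore(v)
        rows.append(v)
    if len(rows) < 2:
        raise ValueError("fewer than 2 usable subjects after exclusions")
    return ArousalTrajectory(np.mean(rows, axis=0), len(rows), modality)


def crossmodal_correlation(annot: ArousalTrajectory,
                           pupil: ArousalTrajectory) -> tuple[float, float]:
    """Pearson r (with two-sided parametric p) between the two group means.

    The parametric p ignores autocorrelation; for inference that respects
    it, use :func:`narousal.isc.circular_shift_pvalue` on the same pair.
    """
    if len(annot) != len(pupil):
        raise ValueError("trajectories must have equal length")
    if annot.values.std() == 0 or pupil.values.std() == 0:
        raise ValueError("cannot correlate a zero-variance trajectory")
    r, p = stats.pearsonr(annot.values, pupil.values)
    return float(r), float(p)
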