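"""Electrode montages and the EEG recording container.

Channel labels and 3-D scalp positions follow the international extended
10-20 system, pulled from MNE's standard montage and rescaled so the
outermost electrode sits at unit radius.  That normalization is what gives
the 0.4 spatial-adjacency distance threshold its meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: 32-channel subset of the extended 10-20 layout used at the default
#: (reduced) cohort scale.  Ordered roughly front to back.
CHANNELS_32 = [
    "Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8",
    "FC1", "FCz", "FC2", "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CPz", "CP2", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

#: Posterior (parieto-occipital) channel group; where the negative
#: low-frequency arousal couplings live in the simulations.
POSTERIOR_32 = ["PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"]

#: Occipital region used for pooled spectra in the rest-vs-movie contrast.
OCCIPITAL = ["PO3", "PO4", "PO7", "PO8", "POz", "O1", "O2", "Oz"]

#: Fronto-central region for the same contrast (subset available at 32 ch).
FRONTO_CENTRAL_32 = ["Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8",
                     "FC1", "FCz", "FC2", "C3", "Cz", "C4"]


@dataclass
class Montage:
    """Named electrodes with unit-sphere-normalized 3-D positions."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), max radius == 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("labels and positions must agree in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, names) -> np.ndarray:
        """Indices of ``names`` in channel order; unknown names raise."""
        lut = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lut[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None


def standard_montage(labels=None) -> Montage:
    """Extended 10-20 montage for the given labels (default 32 channels).

    Positions come from MNE's standard_1020 template and are rescaled so
    the largest electrode radius equals 1.
    """
    import mne  # deferred: mne import is heavy

    if labels is None:
        labels = list(CHANNELS_32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage("standard_1020")
    ch_pos = mont.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in ch_pos]
    if missing:
        raise KeyError(f"labels not in standard 10-20 montage: {missing}")
    pos = np.array([ch_pos[lab] for lab in labels], dtype=float)
    pos /= np.linalg.norm(pos, axis=1).max()
    return Montage(list(labels), pos)


@dataclass
class EegRecording:
    """Multichannel EEG: channels x samples at a stated rate, with montage."""

    data: np.ndarray  # (n_channels, n_samples), microvolt scale
    fs: float
    montage: Montage
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError("data row count must match montage channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must not contain missing samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs
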