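"""Electrode montage handling and template ocular scalp topographies.

The default montage mirrors a 31-electrode 10/20-derived EEG cap plus a
single periocular EOG electrode above the right outer canthus.  Positions
come from the standard 10/20 template shipped with MNE, projected onto the
unit sphere so that inter-electrode distances are comparable across caps.

Vertical eye movements (VEM) project symmetrically onto the fronto-polar
electrodes (Fp1/Fp2); horizontal eye movements (HEM) project with opposite
sign onto the fronto-lateral pair (F7/F8).  ``ocular_topography`` builds
unit-norm template scalp maps with exactly those symmetries; they are used
both as forward-model mixing columns in the simulator and as matching
templates when classifying independent components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np


class ChannelKind(str, Enum):
    EEG = "EEG"
    EOG = "EOG"


@dataclass(frozen=True)
class Channel:
    name: str
    position: np.ndarray  # unit 3-vector, head-centred
    kind: ChannelKind = ChannelKind.EEG


@dataclass
class MontageSpec:
    """Ordered channel list with unit-sphere positions."""

    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def eeg_names(self) -> list[str]:
        return [c.name for c in self.channels if c.kind is ChannelKind.EEG]

    @property
    def eog_names(self) -> list[str]:
        return [c.name for c in self.channels if c.kind is ChannelKind.EOG]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.kind is ChannelKind.EEG]
        )

    def positions(self) -> np.ndarray:
        return np.vstack([c.position for c in self.channels])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tx\ty\tz\tkind\n")
            for c in self.channels:
                x, y, z = c.position
                fh.write(f"{c.name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{c.kind.value}\n")

    @classmethod
    def from_tsv(cls, path) -> "MontageSpec":
        channels = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("name"):
                raise ValueError("montage TSV must start with a name/x/y/z header")
            for line in fh:
                name, x, y, z, kind = line.rstrip("\n").split("\t")
                channels.append(
                    Channel(name, np.array([float(x), float(y), float(z)]),
                            ChannelKind(kind))
                )
        return cls(channels)


#: 31-channel cap layout: 10/20 core plus 10/10 fill-ins, front to back.
DEFAULT_EEG_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2",
)

EOG_NAME = "EOG"
# Above the right outer canthus, below the Fp plane (unit sphere).
_EOG_POSITION = np.array([0.72, 0.62, -0.31])

_VEM_ANCHORS = ("Fp1", "Fp2")
_HEM_ANCHORS = ("F7", "F8")


def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage("standard_1020")
    return {k: np.asarray(v, dtype=float) for k, v in mont.get_positions()["ch_pos"].items()}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length position cannot be normalized")
    return v / n


def make_montage(n_eeg: int = 31, labels: Sequence[str] | None = None) -> MontageSpec:
    """Build an EEG montage of ``n_eeg`` channels plus one EOG channel.

    Parameters
    ----------
    n_eeg
        Number of EEG channels. Labels are taken in cap order from the
        default 31-channel layout unless ``labels`` is given.
    labels
        Explicit EEG label list (must be known 10/20-family labels).
    """
    if n_eeg < 4:
        raise ValueError("montage needs at least 4 EEG channels (Fp1, Fp2, F7, F8)")
    if labels is None:
        if n_eeg <= len(DEFAULT_EEG_LABELS):
            labels = DEFAULT_EEG_LABELS[:n_eeg]
        else:
            raise ValueError(f"default layout has {len(DEFAULT_EEG_LABELS)} labels")
    labels = list(labels)
    if len(labels) != n_eeg:
        raise ValueError("label count does not match n_eeg")
    std = _standard_positions()
    channels = []
    for lab in labels:
        if lab not in std:
            raise ValueError(f"unknown electrode label: {lab!r}")
        channels.append(Channel(lab, _unit(std[lab]), ChannelKind.EEG))
    channels.append(Channel(EOG_NAME, _unit(_EOG_POSITION), ChannelKind.EOG))
    return MontageSpec(channels)


def ocular_topography(montage: MontageSpec, kind: str, sigma: float = 0.55) -> np.ndarray:
    """Template scalp map of an ocular source, unit Euclidean norm.

    ``kind='VEM'``: sum of Gaussian bumps centred on Fp1 and Fp2 — strictly
    symmetric (weight(Fp1) == weight(Fp2) by construction) and decaying with
    chord distance from the fronto-polar anchors.  ``kind='HEM'``: difference
    of bumps centred on F7 and F8 — strictly antisymmetric in the anchor
    pair.  The EOG channel gets weight 0 (templates live in EEG space).

    ``sigma`` is the Gaussian width in unit-sphere chord distance.
    """
    kind = kind.upper()
    if kind == "VEM":
        anchors, signs = _VEM_ANCHORS, (1.0, 1.0)
    elif kind == "HEM":
        anchors, signs = _HEM_ANCHORS, (1.0, -1.0)
    else:
        raise ValueError(f"kind must be 'VEM' or 'HEM', got {kind!r}")
    names = montage.names
    for a in anchors:
        if a not in names:
            raise ValueError(f"montage lacks anchor channel {a!r}")
    pos = montage.positions()
    w = np.zeros(montage.n_channels)
    for a, s in zip(anchors, signs):
        d2 = np.sum((pos - pos[montage.index(a)]) ** 2, axis=1)
        w += s * np.exp(-d2 / (2.0 * sigma**2))
    for i, c in enumerate(montage.channels):
        if c.kind is not ChannelKind.EEG:
            w[i] = 0.0
    return w / np.linalg.norm(w)
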