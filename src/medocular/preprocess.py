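"""Channel-domain cleaning of multichannel EEG recordings.

Implements the standard cleaning chain applied before ocular-component
extraction: zero-phase FIR band-pass (0.9–110 Hz), line-noise notch
(50/100 Hz), average re-referencing over the EEG channels, removal of the
first and last seconds of each task segment, and automatic excision of
high-amplitude artifact sections.  Manual/visual artifact screening is
replaced by a declared amplitude rule: any 1-s window whose peak robust
z-score exceeds a threshold on any channel is removed, so the criterion is
reproducible.

Splice points left by section removal are recorded as zero-length
annotations; the spectral stage drops Welch epochs that straddle them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class Recording:
    """Multichannel time series in microvolts.

    ``data`` is channels x samples; ``annotations`` is a list of
    ``(start_s, end_s, label)`` in the recording's own time base (a
    zero-length ``splice`` annotation marks a concatenation boundary).
    """

    channel_names: list[str]
    fs: float
    data: np.ndarray
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    reference: str = "recording"
    eog_channels: tuple[str, ...] = ("EOG",)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.channel_names) if n not in self.eog_channels]
        )

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def splice_times(self) -> list[float]:
        return [a[0] for a in self.annotations if a[2] == "splice"]

    def copy(self) -> "Recording":
        return replace(
            self,
            channel_names=list(self.channel_names),
            data=self.data.copy(),
            annotations=list(self.annotations),
        )


@dataclass
class SectionMask:
    """Per-sample keep mask produced by artifact-section rejection."""

    keep: np.ndarray
    fs: float

    @property
    def removed_s(self) -> float:
        return float(np.count_nonzero(~self.keep)) / self.fs

    @property
    def removed_fraction(self) -> float:
        return float(np.count_nonzero(~self.keep)) / self.keep.size


def design_bandpass(fs: float, low: float = 0.9, high: float = 110.0) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR band-pass; transition 0.9 Hz at the low
    edge, 10 Hz at the high edge. Applied forward-backward for zero phase."""
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} too low for high edge {high}")
    trans_low, trans_high = 0.9, 10.0
    # Hamming window: ~3.3/N normalized transition width; size by the narrow edge
    numtaps = int(np.ceil(3.3 * fs / trans_low))
    numtaps |= 1  # odd length, type-I linear phase
    return signal.firwin(
        numtaps, [low, high], pass_zero=False, fs=fs, window="hamming"
    )


def fir_bandpass(rec: Recording, low: float = 0.9, high: float = 110.0) -> Recording:
    """Zero-phase FIR band-pass of every channel."""
    taps = design_bandpass(rec.fs, low, high)
    out = rec.copy()
    out.data = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return out


def design_notch(fs: float, center: float, half_width: float = 2.0) -> np.ndarray:
    """Narrow FIR band-stop around one line-noise frequency."""
    if center + half_width >= fs / 2:
        raise ValueError(f"notch at {center} Hz does not fit below Nyquist ({fs/2})")
    numtaps = int(np.ceil(3.3 * fs / half_width)) | 1
    return signal.firwin(
        numtaps,
        [center - half_width, center + half_width],
        fs=fs,
        window="hamming",
    )  # pass_zero default True -> band-stop


def notch_line(
    rec: Recording, base: float = 50.0, harmonics: tuple[float, ...] = (100.0,)
) -> Recording:
    """Notch out mains frequency and its harmonics (zero phase)."""
    if base >= rec.fs / 2:
        raise ValueError("line frequency at or above Nyquist")
    out = rec.copy()
    for f0 in (base, *harmonics):
        taps = design_notch(rec.fs, f0)
        out.data = signal.filtfilt(taps, [1.0], out.data, axis=1)
    return out


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the instantaneous mean of the EEG channels.

    The EOG channel is excluded from the reference computation and left
    untouched (it is referenced periocularly, not on the scalp).
    """
    eeg = rec.eeg_indices()
    if eeg.size < 2:
        raise ValueError("average reference needs at least 2 EEG channels")
    out = rec.copy()
    mean = out.data[eeg].mean(axis=0, keepdims=True)
    out.data[eeg] = out.data[eeg] - mean
    out.reference = "average"
    return out


def trim_task_edges(rec: Recording, edge_s: float = 3.0) -> Recording:
    """Drop the first and last ``edge_s`` seconds of the segment."""
    if edge_s < 0:
        raise ValueError("edge_s must be nonnegative")
    if edge_s == 0:
        return rec.copy()
    n_edge = int(round(edge_s * rec.fs))
    if rec.n_samples <= 2 * n_edge:
        raise ValueError(
            f"recording of {rec.duration_s:.1f}s too short to trim {edge_s}s edges"
        )
    out = rec.copy()
    out.data = rec.data[:, n_edge : rec.n_samples - n_edge]
    out.annotations = [
        (max(a - edge_s, 0.0), min(b - edge_s, out.data.shape[1] / rec.fs), lab)
        for a, b, lab in rec.annotations
        if b - edge_s > 0 and a - edge_s < out.data.shape[1] / rec.fs
    ]
    out.annotations.append((0.0, 0.0, f"trimmed_{edge_s}s_edges"))
    return out


def reject_artifact_sections(
    rec: Recording,
    z_thresh: float = 5.0,
    window_s: float = 1.0,
    detect_band: tuple[float, float] | None = None,
) -> tuple[Recording, SectionMask]:
    """Excise windows with extreme amplitude on any channel.

    Per channel, amplitude is z-scored against the channel median and a
    robust SD (1.4826 * MAD).  Any full window whose peak |z| exceeds
    ``z_thresh`` on any channel is dropped; the survivors are spliced
    together and each splice point annotated.

    ``detect_band`` optionally restricts the *detection* signal to a
    frequency band (the excision still removes the full-band window).
    Muscular artifacts are broadband high-frequency events, so judging
    windows on a 25–110 Hz copy flags them while sparing large slow
    ocular deflections, which an unrestricted amplitude rule would
    excise preferentially.
    """
    win = int(round(window_s * rec.fs))
    if win < 1:
        raise ValueError("window shorter than one sample")
    n_win = rec.n_samples // win
    if n_win == 0:
        raise ValueError("recording shorter than one window")
    if detect_band is not None:
        sos = signal.butter(
            4, [detect_band[0], min(detect_band[1], 0.49 * rec.fs)],
            btype="bandpass", fs=rec.fs, output="sos",
        )
        detect = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        detect = rec.data
    med = np.median(detect, axis=1, keepdims=True)
    mad = np.median(np.abs(detect - med), axis=1, keepdims=True)
    robust_sd = np.where(mad > 0, 1.4826 * mad, np.inf)
    z = np.abs(detect - med) / robust_sd

    keep = np.ones(rec.n_samples, dtype=bool)
    bad_windows = []
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        if np.any(z[:, sl] > z_thresh):
            keep[sl] = False
            bad_windows.append(w)
    # trailing partial window is judged like the others
    tail = slice(n_win * win, rec.n_samples)
    if rec.n_samples > n_win * win and np.any(z[:, tail] > z_thresh):
        keep[tail] = False

    if not keep.any():
        raise ValueError("artifact rejection removed every sample")

    mask = SectionMask(keep=keep, fs=rec.fs)
    out = rec.copy()
    out.data = rec.data[:, keep]
    # splice annotations at every boundary where removed samples were cut out
    out.annotations = [a for a in rec.annotations if a[2].startswith("trimmed")]
    edges = np.flatnonzero(np.diff(keep.astype(int)) == 1) + 1  # removed -> kept
    kept_before = np.cumsum(keep)
    for e in edges:
        t = kept_before[e - 1] / rec.fs
        out.annotations.append((float(t), float(t), "splice"))
    removed = np.flatnonzero(~keep)
    if removed.size:
        out.annotations.append(
            (0.0, 0.0, f"removed_{mask.removed_s:.3f}s_artifact")
        )
    return out, mask


def eog_exclusion_check(artifact_fraction_per_task) -> str:
    """Subject-level EOG exclusion rule.

    A subject's EOG analysis is excluded when more than 25% of any one of
    their four task recordings was artifactual (strict inequality).
    Returns ``"exclude"`` or ``"keep"``.
    """
    fractions = list(artifact_fraction_per_task)
    if len(fractions) != 4:
        raise ValueError("expected exactly 4 task-recording artifact fractions")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"artifact fraction {f} outside [0, 1]")
    return "exclude" if any(f > 0.25 for f in fractions) else "keep"
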