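"""Welch spectra, five-band log power, and the eye-movement count.

Power spectral density is estimated on 1-s Hanning-tapered epochs with no
overlap; epochs that straddle a splice left by artifact-section removal
are dropped rather than tapered.  Spectra are summarised into the five
canonical EEG bands — delta (1–4 Hz), theta (4–8 Hz), alpha (8–12 Hz),
beta (12–25 Hz), gamma (25–110 Hz) — excluding the line-noise regions
around 50 and 100 Hz, and log10-transformed.

The eye-movement count operationalises a simple amplitude rule on the
delta-band-filtered vertical component: an event is a contiguous excursion
beyond 3 SD of the segment's own mean, with excursions closer than 100 ms
merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

LOG_FLOOR = 1e-12


@dataclass
class Spectrum:
    """One-sided Welch PSD (signal-units^2 / Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    epoch_count: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def total_power(self) -> float:
        """Integral of the PSD (Parseval: ~ signal power)."""
        return float(np.sum(self.psd) * self.df)


@dataclass
class BandScheme:
    """Ordered frequency bands with line-noise exclusion windows."""

    bands: Sequence[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("delta", 1.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 12.0),
            ("beta", 12.0, 25.0),
            ("gamma", 25.0, 110.0),
        ]
    )
    exclusions: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(50.0, 2.0), (100.0, 2.0)]
    )

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if hi <= lo:
                raise ValueError(f"band {name}: high edge must exceed low edge")
        highs = [hi for _, _, hi in self.bands]
        lows = [lo for _, lo, _ in self.bands]
        if any(nxt < prev for prev, nxt in zip(highs, lows[1:])):
            raise ValueError("bands must be ordered and non-overlapping")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.bands]


def welch_psd(
    x: np.ndarray,
    fs: float,
    epoch_s: float = 1.0,
    window: str = "hann",
    overlap: float = 0.0,
    splice_times: Iterable[float] | None = None,
) -> Spectrum:
    """Average of per-epoch Hanning-windowed periodograms.

    Epochs are consecutive non-overlapping ``epoch_s`` stretches (the
    default gives 1 Hz resolution at any fs).  An epoch containing a
    splice point strictly in its interior is dropped: it would mix samples
    that were not contiguous in the original recording.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("welch_psd expects a single time series")
    nper = int(round(epoch_s * fs))
    if x.size < nper:
        raise ValueError(f"signal shorter than one epoch ({epoch_s}s)")
    if overlap != 0.0:
        raise NotImplementedError("only non-overlapping epochs are supported")

    win = signal.get_window(window, nper)
    u = np.sum(win**2)  # window power normalisation
    splices = sorted(splice_times) if splice_times else []

    n_epochs = x.size // nper
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    acc = np.zeros(freqs.size)
    used = 0
    for k in range(n_epochs):
        t0, t1 = k * nper / fs, (k + 1) * nper / fs
        if any(t0 < s < t1 for s in splices):
            continue
        seg = x[k * nper : (k + 1) * nper]
        spec = np.fft.rfft(win * seg)
        p = (np.abs(spec) ** 2) / (fs * u)
        p[1:] *= 2.0
        if nper % 2 == 0:
            p[-1] /= 2.0
        acc += p
        used += 1
    if used == 0:
        raise ValueError("every epoch was dropped (splices too dense)")
    return Spectrum(freqs=freqs, psd=acc / used, epoch_count=used)


def band_average(
    spec: Spectrum, scheme: BandScheme | None = None, floor: float = LOG_FLOOR
) -> dict[str, float]:
    """Mean in-band PSD, line-noise bins excluded, log10-transformed.

    Band membership is half-open ``low <= f < high`` so adjacent bands
    never share a bin; bins with ``|f - center| <= half_width`` of an
    exclusion window are omitted.  The mean is floored at ``floor``
    before the log so silent bands stay finite.
    """
    scheme = scheme if scheme is not None else BandScheme()
    f = spec.freqs
    excluded = np.zeros(f.size, dtype=bool)
    for center, hw in scheme.exclusions:
        excluded |= np.abs(f - center) <= hw
    out: dict[str, float] = {}
    for name, lo, hi in scheme.bands:
        if hi > f[-1] + spec.df / 2:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds spectrum range")
        sel = (f >= lo) & (f < hi) & ~excluded
        if not sel.any():
            raise ValueError(f"band {name} has no usable frequency bins")
        out[name] = float(np.log10(max(spec.psd[sel].mean(), floor)))
    return out


def bandpass_series(
    x: np.ndarray, fs: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (robust on short segments)."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def count_eye_movements(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 4.0),
    k: float = 3.0,
    merge_gap_s: float = 0.3,
) -> int:
    """Number of supra-threshold excursions of the band-filtered signal.

    The signal is band-passed to ``band`` (delta by default), then an
    event is a maximal run of samples with ``|x - mean| > k * SD``, the
    mean and SD being those of the filtered segment itself (the criterion
    is therefore invariant under positive affine rescaling).  Runs closer
    than ``merge_gap_s`` are merged into one event: a band-limited
    deflection rings on the scale of one band period (~300 ms at the
    upper delta edge), so excursions closer than that are lobes of the
    same physical event, not separate movements.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("need at least one second of signal")
    filt = bandpass_series(x, fs, band[0], band[1])
    sd = filt.std()
    if sd <= 1e-10 * max(1.0, np.abs(x).max()):
        return 0  # constant input up to numerical filter residue
    above = np.abs(filt - filt.mean()) > k * sd
    if not above.any():
        return 0
    # run-length encode the boolean series
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = edges[::1][np.diff(above.astype(int))[edges] == 1] + 1
    ends = edges[np.diff(above.astype(int))[edges] == -1] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    gap = int(round(merge_gap_s * fs))
    count = 1
    for i in range(1, starts.size):
        if starts[i] - ends[i - 1] >= gap:
            count += 1
    return count
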