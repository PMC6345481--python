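"""Synthetic cohorts and EEG recordings with known ground truth.

No recordings from the original study are available, so validation runs on
a forward model that reproduces the statistical structure the analysis
assumes: a 31-channel 10/20 EEG at 250 Hz plus one EOG channel, 7-minute
task segments, ocular sources embedded as saccade-shaped event trains whose
rate is higher under instructed mind-wandering (IMW) than under
focused-attention meditation (FAM), and a latent per-subject ocular
amplitude that decays with meditation expertise.

Event-rate defaults keep the FAM:IMW contrast of the study's printed
per-task eye-movement counts (45.5 vs 57.8 detected events per ~414 s
task, a ratio of ~1.27).  The base rates are set higher than the detected
counts (0.20 vs 0.26 Hz): a 3-SD amplitude criterion only counts the
largest excursions, so true generative saccade rates necessarily exceed
detected ones, and spontaneous closed-eye saccade rates of a few tenths
of a hertz are physiologically typical.

Everything is seeded: the same (spec, seed) pair reproduces a session
byte-for-byte, and the returned :class:`GroundTruth` carries the exact
source time courses, mixing columns, event times, and sensor noise so every
downstream stage can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal, stats

from .montage import MontageSpec, make_montage, ocular_topography
from .preprocess import Recording

Task = Literal["FAM", "IMW"]
Condition = Literal["CPL", "SEP"]

TASKS: tuple[Task, ...] = ("FAM", "IMW")
CONDITIONS: tuple[Condition, ...] = ("CPL", "SEP")


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated meditator."""

    id: str
    weekly_practice_min: float
    years_since_course: float
    ocular_scale: float
    seed: int

    def __post_init__(self) -> None:
        if self.weekly_practice_min < 0 or self.years_since_course < 0:
            raise ValueError("practice and years must be nonnegative")
        if self.ocular_scale <= 0:
            raise ValueError("ocular_scale must be positive")

    @property
    def expertise_index(self) -> float:
        return self.weekly_practice_min * self.years_since_course


@dataclass(frozen=True)
class SegmentSpec:
    """One task segment of the 2x2 within-subject design."""

    task: Task
    condition: Condition
    duration_s: float = 420.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")


@dataclass
class SimParams:
    """Forward-model knobs (amplitudes in microvolts, rates in Hz).

    The per-task saccade rates are the study conditions of the simulation;
    the remaining knobs set a signal-to-noise regime in which the group
    effect is detectable at n = 24 subjects.
    """

    rate_fam_hz: float = 0.20
    rate_imw_hz: float = 0.26
    vem_amp_uv: float = 200.0
    hem_amp_uv: float = 100.0
    amp_sigma: float = 0.3          # lognormal spread of single-event amplitude
    rise_s: float = 0.03            # saccade step rise
    decay_s: float = 0.20           # exponential return to baseline
    n_neural: int = 8
    neural_rms_uv: float = 15.0
    alpha_freq_hz: float = 10.0
    alpha_rel_amp: float = 1.0      # alpha amplitude relative to 1/f RMS
    sensor_noise_uv: float = 2.0
    eog_vem_gain: float = 1.0
    eog_hem_gain: float = 0.6
    ocular_enabled: bool = True

    def rate(self, task: Task) -> float:
        return self.rate_fam_hz if task == "FAM" else self.rate_imw_hz


@dataclass
class GroundTruth:
    """Exact generative state of one simulated session."""

    vem_source: np.ndarray
    hem_source: np.ndarray
    neural_sources: np.ndarray           # (n_neural, n_samples)
    mixing: np.ndarray                   # (n_channels, 2 + n_neural)
    vem_events: list[float]
    hem_events: list[float]
    sensor_noise: np.ndarray             # (n_channels, n_samples)
    fs: float

    def sources(self) -> np.ndarray:
        return np.vstack([self.vem_source, self.hem_source, self.neural_sources])


def generate_cohort(
    n: int,
    seed: int,
    practice_mean: float = 102.59,
    practice_sd: float = 67.60,
    years_mean: float = 2.31,
    years_sd: float = 1.60,
    gamma: float = 1.0,
    scale_base: float = 1.0,
    scale_noise_sigma: float = 0.2,
) -> list[SubjectSpec]:
    """Draw ``n`` subjects with the cohort's practice/experience moments.

    Weekly practice (min/week) and years since training are sampled from
    normals truncated at zero with the stated location/scale (both
    quantities are nonnegative).  The latent ocular amplitude multiplier
    decays hyperbolically with the expertise index (practice x years):

        ocular_scale = scale_base / (1 + gamma * index / 1000) * lognormal

    which reproduces the observed negative expertise-activity association
    in direction without asserting its magnitude.
    """
    if n < 0:
        raise ValueError("cohort size must be nonnegative")
    rng = np.random.default_rng(seed)
    practice = stats.truncnorm.rvs(
        -practice_mean / practice_sd, np.inf, loc=practice_mean, scale=practice_sd,
        size=n, random_state=rng,
    )
    years = stats.truncnorm.rvs(
        -years_mean / years_sd, np.inf, loc=years_mean, scale=years_sd,
        size=n, random_state=rng,
    )
    noise = rng.lognormal(mean=0.0, sigma=scale_noise_sigma, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for i in range(n):
        index = practice[i] * years[i]
        scale = scale_base / (1.0 + gamma * index / 1000.0) * noise[i]
        cohort.append(
            SubjectSpec(
                id=f"S{i + 1:03d}",
                weekly_practice_min=float(practice[i]),
                years_since_course=float(years[i]),
                ocular_scale=float(scale),
                seed=int(seeds[i]),
            )
        )
    return cohort


def saccade_kernel(fs: float, rise_s: float = 0.03, decay_s: float = 0.15) -> np.ndarray:
    """Unit-peak saccade-shaped waveform: linear rise, exponential return."""
    n_rise = max(int(round(rise_s * fs)), 1)
    n_decay = max(int(round(5 * decay_s * fs)), 1)
    rise = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    decay = np.exp(-np.arange(n_decay) / (decay_s * fs))
    return np.concatenate([rise, decay])


def simulate_ocular_source(
    rng: np.random.Generator,
    duration_s: float,
    fs: float,
    rate_hz: float,
    amp_uv: float,
    amp_sigma: float = 0.3,
    rise_s: float = 0.03,
    decay_s: float = 0.15,
) -> tuple[np.ndarray, list[float]]:
    """Poisson saccade train convolved with the saccade waveform.

    Event amplitudes are lognormal around ``amp_uv`` with random sign
    (the eyes move in both directions). Returns the source time course and
    the exact event onset times in seconds.
    """
    n = int(round(duration_s * fs))
    n_events = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    amps = amp_uv * rng.lognormal(mean=0.0, sigma=amp_sigma, size=n_events)
    amps *= rng.choice([-1.0, 1.0], size=n_events)
    impulses = np.zeros(n)
    idx = np.minimum((times * fs).astype(int), n - 1)
    np.add.at(impulses, idx, amps)
    kern = saccade_kernel(fs, rise_s, decay_s)
    source = signal.fftconvolve(impulses, kern)[:n]
    return source, [float(t) for t in times]


def pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    return x / np.std(x)


def _neural_source(rng: np.random.Generator, n: int, fs: float, params: SimParams) -> np.ndarray:
    t = np.arange(n) / fs
    x = pink_noise(rng, n, fs)
    phase = rng.uniform(0, 2 * np.pi)
    amp = params.alpha_rel_amp * rng.uniform(0.5, 1.5)
    x = x + amp * np.sin(2 * np.pi * params.alpha_freq_hz * t + phase)
    return params.neural_rms_uv * x / np.std(x)


def simulate_session(
    subject: SubjectSpec,
    segment: SegmentSpec,
    montage: MontageSpec | None = None,
    seed: int | None = None,
    params: SimParams | None = None,
) -> tuple[Recording, GroundTruth]:
    """Forward-model one task segment for one subject.

    Channel data = mixing @ sources + sensor noise, exactly:

    * ocular sources: VEM and HEM saccade trains at the task's rate,
      scaled by the subject's latent ``ocular_scale``;
    * their mixing columns are the template scalp topographies, plus the
      declared VEM/HEM gains on the EOG row (a single periocular electrode
      picks up combined vertical and horizontal movements);
    * neural background: ``n_neural`` sources of 1/f noise plus a 10 Hz
      alpha component with random phase, mixed through random unit-norm
      EEG-only columns;
    * independent white sensor noise on every channel.

    The seed defaults to a combination of the subject's own seed and the
    segment identity, so the four segments of one subject differ but the
    whole session is reproducible.
    """
    montage = montage if montage is not None else make_montage(31)
    params = params if params is not None else SimParams()
    if seed is None:
        seed_key = [subject.seed, TASKS.index(segment.task), CONDITIONS.index(segment.condition)]
    else:
        seed_key = [seed]
    rng = np.random.default_rng(seed_key)

    n = int(round(segment.duration_s * segment.fs))
    n_ch = montage.n_channels
    rate = params.rate(segment.task)

    if params.ocular_enabled:
        vem, vem_events = simulate_ocular_source(
            rng, segment.duration_s, segment.fs, rate,
            params.vem_amp_uv * subject.ocular_scale, params.amp_sigma,
            params.rise_s, params.decay_s,
        )
        hem, hem_events = simulate_ocular_source(
            rng, segment.duration_s, segment.fs, rate,
            params.hem_amp_uv * subject.ocular_scale, params.amp_sigma,
            params.rise_s, params.decay_s,
        )
    else:
        vem = np.zeros(n)
        hem = np.zeros(n)
        vem_events, hem_events = [], []

    neural = np.vstack(
        [_neural_source(rng, n, segment.fs, params) for _ in range(params.n_neural)]
    ) if params.n_neural else np.empty((0, n))

    eeg_idx = montage.eeg_indices()
    eog_row = montage.index(montage.eog_names[0]) if montage.eog_names else None

    mixing = np.zeros((n_ch, 2 + params.n_neural))
    mixing[:, 0] = ocular_topography(montage, "VEM")
    mixing[:, 1] = ocular_topography(montage, "HEM")
    if eog_row is not None:
        mixing[eog_row, 0] = params.eog_vem_gain
        mixing[eog_row, 1] = params.eog_hem_gain
    for k in range(params.n_neural):
        col = np.zeros(n_ch)
        v = rng.standard_normal(eeg_idx.size)
        col[eeg_idx] = v / np.linalg.norm(v)
        mixing[:, 2 + k] = col

    noise = params.sensor_noise_uv * rng.standard_normal((n_ch, n))
    sources = np.vstack([vem, hem, neural])
    data = mixing @ sources + noise

    rec = Recording(
        channel_names=montage.names,
        fs=segment.fs,
        data=data,
        annotations=[],
        reference="recording",
        eog_channels=tuple(montage.eog_names),
    )
    truth = GroundTruth(
        vem_source=vem,
        hem_source=hem,
        neural_sources=neural,
        mixing=mixing,
        vem_events=vem_events,
        hem_events=hem_events,
        sensor_noise=noise,
        fs=segment.fs,
    )
    return rec, truth


def design_segments(duration_s: float = 420.0, fs: float = 250.0) -> list[SegmentSpec]:
    """The 2x2 within-subject design: two tasks in two settings."""
    return [
        SegmentSpec(task=t, condition=c, duration_s=duration_s, fs=fs)
        for c in CONDITIONS
        for t in TASKS
    ]
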