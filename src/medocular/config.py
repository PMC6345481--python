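"""Study configuration: one serializable object drives a full run.

Every random stage derives its seed deterministically from the global
seed, so a persisted config reproduces its report exactly.  The config
round-trips through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .synth import SimParams


@dataclass
class PreprocessParams:
    band_low_hz: float = 0.9
    band_high_hz: float = 110.0
    notch_base_hz: float = 50.0
    notch_harmonics: tuple[float, ...] = (100.0,)
    edge_trim_s: float = 3.0
    artifact_z_thresh: float = 12.0
    artifact_window_s: float = 1.0
    artifact_detect_band: tuple[float, float] | None = (25.0, 110.0)
    drop_channels: tuple[str, ...] = ()


@dataclass
class IcaParams:
    rank: int | None = None        # None -> channels - 1
    max_iter: int = 200
    tol: float = 1e-7
    score_threshold: float = 0.80


@dataclass
class StatsParams:
    alpha: float = 0.05
    mde_power: float = 0.80


@dataclass
class StudyConfig:
    """Complete description of a simulated study run."""

    n_subjects: int = 24
    duration_s: float = 420.0
    fs: float = 250.0
    n_eeg: int = 31
    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    ica: IcaParams = field(default_factory=IcaParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, typ in (
            ("sim", SimParams),
            ("preprocess", PreprocessParams),
            ("ica", IcaParams),
            ("stats", StatsParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def test_scale_config(seed: int = 0) -> StudyConfig:
    """Reduced problem size for continuous-integration runs.

    Shorter segments and a 12-dimensional ICA subspace (the forward model
    has 10 sources, so rank 12 retains them all) keep a full-study run in
    the tens of seconds.
    """
    cfg = StudyConfig(n_subjects=8, duration_s=120.0, seed=seed)
    cfg.ica = IcaParams(rank=12, max_iter=100)
    return cfg
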