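"""Configuration dataclasses for simulation, preprocessing and pipeline runs.

All configs are plain dataclasses that round-trip through YAML, so a run
is fully described by one file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "PreprocessingConfig",
    "SegmentationConfig",
    "ModerationConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


def _default_transition_weights(k: int) -> list[list[float]]:
    w = np.ones((k, k))
    np.fill_diagonal(w, 0.0)
    return w.tolist()


@dataclass
class SimulationConfig:
    """Parameters of one simulated resting-state recording.

    Defaults follow a typical 64-channel, 500 Hz, 6-minute eyes-open
    session with four quasi-stable topographies whose dwell times are in
    the tens of milliseconds.
    """

    n_channels: int = 64
    n_states: int = 4
    sampling_rate: float = 500.0
    record_duration: float = 360.0
    mean_dwell: float = 80.0          # ms
    dwell_shape: float = 2.0          # gamma shape; mode > 0 for shape > 1
    transition_weights: list[list[float]] | None = None
    alpha_freq: float = 10.0          # Hz
    snr: float = 3.0                  # signal RMS / noise RMS; inf = noiseless
    noise_sd: float = 5.0             # μV, sensor-noise scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_weights is None:
            self.transition_weights = _default_transition_weights(self.n_states)
        w = np.asarray(self.transition_weights, dtype=float)
        if w.shape != (self.n_states, self.n_states):
            raise ValueError("transition_weights must be K x K")
        if np.any(w < 0):
            raise ValueError("transition_weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("transition_weights diagonal must be zero")
        if self.n_states > 1 and np.any(w.sum(axis=1) <= 0):
            raise ValueError("every transition_weights row needs a positive entry")
        n = self.record_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("record_duration x sampling_rate must be an integer")
        if self.n_states < 1 or self.n_channels < 2:
            raise ValueError("need n_states >= 1 and n_channels >= 2")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_duration * self.sampling_rate))

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.transition_weights, dtype=float)


@dataclass
class CohortConfig:
    """Behavioral-cohort parameters with planted moderation effects.

    ``effect_map`` entries are ``(parameter_name, b1, b2, b3)``: the named
    microstate parameter X enters the creativity score as
    ``b1*Xc + b2*Wc + b3*Xc*Wc`` with W the self-esteem total and both
    centered. Defaults describe an undergraduate cohort: self-esteem mean
    28.37 (sd 2.81) on the 10-40 scale, 72% male, age 18.3 +/- 0.84 years.
    """

    n_subjects: int = 50
    rses_mean: float = 28.37
    rses_sd: float = 2.81
    male_prob: float = 0.72
    age_mean: float = 18.3
    age_sd: float = 0.84
    effect_map: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: [("duration_ms2", 0.0, 1.0, -0.06)]
    )
    wcts_intercept: float = 100.0
    sex_effect: float = 0.0
    age_effect: float = 0.0
    noise_sd: float = 10.0            # residual sd of the creativity total
    dwell_spread: float = 0.15        # lognormal sigma of per-subject dwell scaling
    weight_spread: float = 0.20      # lognormal sigma of transition-weight scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_prob <= 1.0:
            raise ValueError("male_prob must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        self.effect_map = [tuple(e) for e in self.effect_map]


@dataclass
class PreprocessingConfig:
    l_freq: float = 2.0
    h_freq: float = 20.0
    filter_order: int = 4
    epoch_ms: float = 2000.0
    reject_uv: float = 80.0
    # the +/- threshold is applied to absolute per-sample amplitude, not
    # peak-to-peak; ICA-based artifact removal is intentionally absent
    rejection_mode: str = "absolute"
    ica: bool = False


@dataclass
class SegmentationConfig:
    k_range: list[int] = field(default_factory=lambda: list(range(1, 9)))
    # fixed model order (the conventional four microstate classes);
    # set to None to select k by the cross-validation criterion instead
    k_fixed: int | None = 4
    max_peaks: int = 5000
    level: str = "group"              # "group" (two-level) or "pooled"


@dataclass
class ModerationConfig:
    alpha: float = 0.05
    outlier_sd: float = 3.0
    probe_sds: float = 1.0


@dataclass
class RunConfig:
    """Full pipeline configuration: simulate -> preprocess -> segment ->
    backfit -> moderate."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    moderation: ModerationConfig = field(default_factory=ModerationConfig)
    seed: int = 0
    output_dir: str = "msmod_run"


_SECTIONS = {
    "simulation": SimulationConfig,
    "cohort": CohortConfig,
    "preprocessing": PreprocessingConfig,
    "segmentation": SegmentationConfig,
    "moderation": ModerationConfig,
}


def to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def load_config(path: str | Path, cls=RunConfig):
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if cls is RunConfig:
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            if name in raw:
                kwargs[name] = section_cls(**raw.pop(name))
        kwargs.update(raw)
        return RunConfig(**kwargs)
    return cls(**raw)
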