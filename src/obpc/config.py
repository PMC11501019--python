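"""Run configuration: defaults, YAML loading, validation.

Every analysis parameter with a stated value in the study design keeps
that value as its default (50 Hz notch, z = 7 rejection, tertile
classes, 4-100 Hz, 2 coherence / 7 Granger tapers, 80% of f and 5 Hz
smoothing, 121-sample searchlight with the 10-neighbor rule, 5,000
permutations, p < 0.01 decoding clusters, p < 0.05 Granger clusters,
200 ms onset delay).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with study defaults."""

    # experiment
    label: str = "synthetic"
    seed: int = 0
    n_participants: int = 20
    n_trials: int = 180

    # preprocessing
    line_freq: float = 50.0
    z_thresh: float = 7.0
    onset_delay: float = 0.200

    # spectral grids
    fmin: float = 4.0
    fmax: float = 100.0
    f_step: float = 1.0
    t_start: float = -0.4
    t_stop: float = 1.4
    t_step: float = 0.025
    coherence_tapers: int = 2
    bandwidth_frac: float = 0.8
    min_cycles: float = 2.0

    # granger
    gc_window: tuple = (0.0, 1.0)
    gc_bandwidth: float = 5.0
    gc_tapers: int = 7
    gc_min_trials: int = 10
    gc_alpha: float = 0.05

    # decoding
    searchlight_half_width: int = 5
    min_neighbors: int = 10
    n_perm: int = 5000
    cluster_alpha: float = 0.01
    svm_C: float = 1.0
    sequential_permutations: bool = True

    def __post_init__(self):
        if self.n_perm <= 0:
            raise ValueError("n_perm must be positive")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must lie in (0, 1)")
        if not 0 < self.gc_alpha < 1:
            raise ValueError("gc_alpha must lie in (0, 1)")
        if self.fmax <= self.fmin or self.t_stop <= self.t_start:
            raise ValueError("empty analysis grid")
        if self.n_trials % 3:
            raise ValueError("n_trials must be divisible by 3")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gc_window"] = list(self.gc_window)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gc_window" in raw:
            raw["gc_window"] = tuple(raw["gc_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
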