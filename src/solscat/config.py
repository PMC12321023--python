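"""Run configuration: one flat record of every tunable, serializable as
simple ``key = value`` text so runs are reproducible from a config file."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .hydration import HydrationParams

__all__ = ["RunConfig"]

_EXV_MODES = ("simple", "fraser", "grid")


@dataclass
class RunConfig:
    """All knobs of a profile calculation / fit (lengths in A)."""

    exv_mode: str = "simple"
    cell_width: float = 1.0
    bin_width: float = 0.1
    weighted_bins: bool = True
    hydrate: bool = True
    volume_table: str = "minimum_fluctuation"
    rho0: float = 0.334
    simple_radius: float = 1.62
    fit_surface: bool = True  # grid model: fit the exterior-layer scale
    fit_background: bool = True
    q_min: float = 0.001
    q_max: float = 1.0
    n_q: int = 100
    # hydration
    n_directions: int = 26
    offset_delta: float = -0.5
    jitter_sigma: float = 0.5
    water_radius: float = 1.4
    acceptance_threshold: float = 0.7
    hydration_seed: int = 0
    # optimizer
    optimizer_seed: int = 0
    optimizer_budget: int = 200

    def __post_init__(self):
        if self.exv_mode not in _EXV_MODES:
            raise ValueError(f"exv_mode must be one of {_EXV_MODES}")
        for name in ("cell_width", "bin_width", "rho0", "simple_radius",
                     "water_radius", "q_min", "q_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_q < 2 or self.q_max <= self.q_min:
            raise ValueError("q grid must have n_q >= 2 and q_max > q_min")
        if self.optimizer_budget < 10:
            raise ValueError("optimizer_budget must be >= 10")

    def hydration_params(self) -> HydrationParams:
        return HydrationParams(
            n_directions=self.n_directions,
            offset_delta=self.offset_delta,
            jitter_sigma=self.jitter_sigma,
            water_radius=self.water_radius,
            acceptance_threshold=self.acceptance_threshold,
            rng_seed=self.hydration_seed)

    # -- key = value serialization -----------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def save(self, path):
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"str": str, "float": float, "int": int,
                 "bool": lambda s: s.strip().lower() in ("1", "true", "yes")}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[key] = casts[str(types[key])](value.strip())
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())
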