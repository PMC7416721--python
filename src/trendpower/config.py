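"""Structured run configuration for grid sweeps (TOML or YAML)."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import ScenarioGridConfig, default_grid_config
from .trend_fit import APPROACHES

__all__ = ["RunConfig", "parse_config"]

_KNOWN_KEYS = {
    "seed",
    "approaches",
    "alphas",
    "n_reps",
    "em_variant",
    "xi",
    "n_jobs",
    "grid",
    "out",
    "log_level",
}
_KNOWN_GRID_KEYS = {"T_values", "r_values", "cv_settings"}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of a Monte Carlo grid sweep."""

    seed: int = 0
    approaches: tuple = APPROACHES
    alphas: tuple = (0.05, 0.20)
    n_reps: int = 10_000
    em_variant: str = "with_variance"
    xi: float = 0.025
    n_jobs: int = 1
    grid: ScenarioGridConfig = field(default_factory=default_grid_config)
    out: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for a in self.approaches:
            if a not in APPROACHES:
                raise ValueError(f"unknown approach {a!r}")
        for alpha in self.alphas:
            if not 0 < alpha < 1:
                raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        if self.em_variant not in ("map", "with_variance"):
            raise ValueError(f"unknown em_variant {self.em_variant!r}")
        if not 0 < self.xi < 0.5:
            raise ValueError("xi must lie in (0, 0.5)")
        object.__setattr__(self, "approaches", tuple(self.approaches))
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {
            "T_values": list(self.grid.T_values),
            "r_values": [float(r) for r in self.grid.r_values],
            "cv_settings": [list(cv) for cv in self.grid.cv_settings],
        }
        d["approaches"] = list(self.approaches)
        d["alphas"] = list(self.alphas)
        return d


def _load_raw(path: Path) -> dict:
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    raise ValueError(f"unsupported config format: {path.suffix!r} (use .toml or .yaml)")


def parse_config(path) -> RunConfig:
    """Load and validate a run configuration, filling defaults.

    Unknown keys are an error (listed by name), so typos never silently
    fall back to defaults.  An empty file yields the full default config.
    """
    path = Path(path)
    raw = _load_raw(path)
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "grid" in kwargs and kwargs["grid"] is not None:
        graw = kwargs["grid"]
        unknown = set(graw) - _KNOWN_GRID_KEYS
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        defaults = default_grid_config()
        kwargs["grid"] = ScenarioGridConfig(
            T_values=tuple(graw.get("T_values", defaults.T_values)),
            r_values=tuple(graw.get("r_values", defaults.r_values)),
            cv_settings=tuple(tuple(cv) for cv in graw.get("cv_settings", defaults.cv_settings)),
        )
    return RunConfig(**kwargs)
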