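"""Flat run configuration: one file, one reproducible run.

The config format is a flat ``key: value`` mapping (YAML subset).  Unknown
keys are an error; every value is validated against its owning type's
constraints before any computation starts.  ``load_config`` on an empty or
missing-field file fills documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .grn_core import GrnParameters

__all__ = ["RunConfig", "load_config", "dump_defaults"]


@dataclass(frozen=True)
class RunConfig:
    # spatial scaffold
    grid_n_points: int = 101
    fgf_plateau_level: float = 1.0
    fgf_plateau_fraction: float = 0.30
    fgf_baseline_level: float = 0.05
    fgf_shape: str = "exponential"
    pole_width: float = 0.15
    competence_soft: bool = False
    # solver
    solver_rtol: float = 1e-7
    solver_atol: float = 1e-10
    kymo_dt: float = 0.25
    # analysis
    detection_fraction: float = 0.2
    min_domain_width: float = 0.05
    # cohort
    n_embryos: int = 10
    ears_per_embryo: int = 2
    parameter_jitter_cv: float = 0.1
    measurement_noise_sd: float = 3.0
    seed: int = 0
    # network kinetics
    grn: GrnParameters = field(default_factory=GrnParameters)

    def __post_init__(self) -> None:
        if self.grid_n_points < 11:
            raise ValueError("grid_n_points must be >= 11")
        if not 0.0 < self.fgf_plateau_fraction < 1.0:
            raise ValueError(
                f"fgf_plateau_fraction={self.fgf_plateau_fraction} "
                "violates the (0, 1) constraint"
            )
        if not self.fgf_plateau_level > self.fgf_baseline_level >= 0.0:
            raise ValueError("require fgf_plateau_level > fgf_baseline_level >= 0")
        if self.fgf_shape not in ("linear", "exponential"):
            raise ValueError("fgf_shape must be 'linear' or 'exponential'")
        if not 0.0 < self.pole_width < 0.5:
            raise ValueError("pole_width violates the (0, 0.5) constraint")
        if self.solver_rtol <= 0 or self.solver_atol <= 0 or self.kymo_dt <= 0:
            raise ValueError("solver tolerances and kymo_dt must be > 0")
        if not 0.0 < self.detection_fraction <= 1.0:
            raise ValueError("detection_fraction violates the (0, 1] constraint")
        if self.min_domain_width <= 0:
            raise ValueError("min_domain_width must be > 0")
        if self.n_embryos <= 0 or self.ears_per_embryo <= 0:
            raise ValueError("cohort counts must be positive")
        if self.parameter_jitter_cv < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def flat_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name == "grn":
                out.update(self.grn.as_dict())
            else:
                out[f.name] = getattr(self, f.name)
        return out

    def resolved_text(self) -> str:
        """Full resolved configuration, echoed verbatim into run logs."""
        return "".join(f"{k}: {v}\n" for k, v in sorted(self.flat_dict().items()))


_GRN_KEYS = {f.name for f in fields(GrnParameters)}
_TOP_KEYS = {f.name for f in fields(RunConfig)} - {"grn"}


def _coerce(value):
    """YAML 1.1 leaves numbers like '1.0e-6' as strings; recover them."""
    if isinstance(value, str):
        for cast in (int, float):
            try:
                return cast(value)
            except ValueError:
                continue
    return value


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read and validate a flat config file; ``None`` yields all defaults."""
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a flat key: value mapping")
        raw = loaded
    top: dict = {}
    grn: dict = {}
    for key, value in raw.items():
        if key in _GRN_KEYS:
            grn[key] = _coerce(value)
        elif key in _TOP_KEYS:
            top[key] = _coerce(value)
        else:
            raise ValueError(
                f"unknown config key {key!r}; valid keys: "
                f"{', '.join(sorted(_TOP_KEYS | _GRN_KEYS))}"
            )
    return RunConfig(grn=GrnParameters(**grn), **top)


def dump_defaults() -> str:
    return RunConfig().resolved_text()
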