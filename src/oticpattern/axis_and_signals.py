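"""Spatial scaffold for the otic anteroposterior axis.

The model abstracts the medial edge of the zebrafish otic vesicle to a single
normalised axis: position 0 is the anterior pole, position 1 the posterior
pole.  Three extrinsic structures live on this axis:

* an anterior-to-posterior gradient of extrinsic Fgf protein (``Fgf_e``),
  high over an anterior plateau (rhombomere 4 abuts the anterior ~30% of the
  vesicle) and declining beyond it;
* a competence mask for intrinsic *fgf* expression, equal to 1 at the two
  poles and 0 in the centre;
* a spatially uniform, piecewise-constant-in-time Hedgehog input (``Hh_e``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AxisGrid",
    "ExtrinsicFgfProfile",
    "CompetenceMask",
    "HhSchedule",
    "make_grid",
    "build_extrinsic_fgf",
    "build_competence",
    "hh_level_at",
]

MIN_GRID_POINTS = 11

GradientShape = Literal["linear", "exponential"]

#: fraction of the (plateau - baseline) excess still present at position 1
#: for the exponential shape; sets the decay length constant.
EXP_TAIL_FRACTION = 0.05


@dataclass(frozen=True)
class AxisGrid:
    """Uniform discretisation of the normalised anteroposterior axis."""

    n_points: int
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if self.n_points < MIN_GRID_POINTS:
            raise ValueError(
                f"n_points={self.n_points} is below the minimum of "
                f"{MIN_GRID_POINTS} spatial samples"
            )
        if pos.shape != (self.n_points,):
            raise ValueError("positions length does not match n_points")
        if not (np.all(np.diff(pos) > 0) and pos[0] == 0.0 and pos[-1] == 1.0):
            raise ValueError("positions must increase strictly from 0 to 1")
        object.__setattr__(self, "positions", pos)

    @property
    def spacing(self) -> float:
        return 1.0 / (self.n_points - 1)


@dataclass(frozen=True)
class ExtrinsicFgfProfile:
    """Static extrinsic Fgf gradient ``Fgf_e(x)`` on a grid (a.u.)."""

    grid: AxisGrid
    plateau_level: float
    plateau_fraction: float
    baseline_level: float
    shape: GradientShape
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.positions.shape:
            raise ValueError("values length does not match grid")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("extrinsic Fgf profile must be non-increasing")
        if np.any(v < self.baseline_level - 1e-12):
            raise ValueError("extrinsic Fgf profile fell below baseline_level")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CompetenceMask:
    """Per-position competence ``C(x)`` for intrinsic *fgf* induction."""

    grid: AxisGrid
    pole_width: float
    soft: bool
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.positions.shape:
            raise ValueError("weights length does not match grid")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("competence weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class HhSchedule:
    """Uniform extracellular Hh level with timed overrides.

    ``intervals`` is a list of ``(t_start, t_end, level)`` triples in hpf;
    outside every interval the level equals ``baseline_level``.
    """

    baseline_level: float
    intervals: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.baseline_level < 0:
            raise ValueError("baseline_level must be >= 0")
        ivs = tuple(tuple(map(float, iv)) for iv in self.intervals)
        for t0, t1, level in ivs:
            if t1 <= t0:
                raise ValueError(f"empty Hh override interval ({t0}, {t1})")
            if level < 0:
                raise ValueError("Hh override level must be >= 0")
        for (a0, a1, _), (b0, b1, _) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError("Hh override intervals must not overlap")
        object.__setattr__(self, "intervals", ivs)

    def boundaries(self) -> list[float]:
        """All interval edges, for event-aware integration."""
        out: list[float] = []
        for t0, t1, _ in self.intervals:
            out.extend((t0, t1))
        return out


def make_grid(n_points: int) -> AxisGrid:
    """Uniform axis grid with ``n_points`` samples from 0 to 1."""
    if n_points < MIN_GRID_POINTS:
        raise ValueError(
            f"n_points={n_points} is below the minimum of {MIN_GRID_POINTS}"
        )
    return AxisGrid(n_points=n_points, positions=np.linspace(0.0, 1.0, n_points))


def build_extrinsic_fgf(
    grid: AxisGrid,
    plateau_level: float = 1.0,
    plateau_fraction: float = 0.30,
    baseline_level: float = 0.05,
    shape: GradientShape = "exponential",
) -> ExtrinsicFgfProfile:
    """Construct the extrinsic Fgf gradient.

    The profile equals ``plateau_level`` for every position up to
    ``plateau_fraction`` and declines beyond it, either linearly to
    ``baseline_level`` at position 1 or exponentially with a length constant
    chosen so only ``EXP_TAIL_FRACTION`` of the excess over baseline remains
    at position 1.
    """
    if not 0.0 < plateau_fraction < 1.0:
        raise ValueError("plateau_fraction must lie in (0, 1)")
    if not plateau_level > baseline_level >= 0.0:
        raise ValueError(
            "require plateau_level > baseline_level >= 0 "
            f"(got {plateau_level!r}, {baseline_level!r})"
        )
    x = grid.positions
    excess = plateau_level - baseline_level
    tail = np.clip(x - plateau_fraction, 0.0, None)
    if shape == "linear":
        span = 1.0 - plateau_fraction
        values = np.maximum(plateau_level - excess * tail / span, baseline_level)
    elif shape == "exponential":
        lam = (1.0 - plateau_fraction) / np.log(1.0 / EXP_TAIL_FRACTION)
        values = baseline_level + excess * np.exp(-tail / lam)
    else:
        raise ValueError(f"unknown gradient shape {shape!r}")
    values = np.where(x <= plateau_fraction + 1e-12, plateau_level, values)
    return ExtrinsicFgfProfile(
        grid=grid,
        plateau_level=plateau_level,
        plateau_fraction=plateau_fraction,
        baseline_level=baseline_level,
        shape=shape,
        values=values,
    )


def build_competence(
    grid: AxisGrid, pole_width: float = 0.15, soft: bool = False
) -> CompetenceMask:
    """Pole-restricted competence mask, symmetric about position 0.5.

    Hard mask: 1 for ``x <= pole_width`` or ``x >= 1 - pole_width``, else 0.
    Soft mask: cosine ramp of half the pole width on the inner flank.
    """
    if not 0.0 < pole_width < 0.5:
        raise ValueError(
            f"pole_width={pole_width} invalid: must lie in (0, 0.5) "
            "(at 0.5 the two poles would merge)"
        )
    x = grid.positions
    n = grid.n_points
    # build the anterior half and mirror it, so symmetry is bit-exact
    half = (n + 1) // 2
    d = x[:half]  # distance to the anterior pole
    if soft:
        ramp = pole_width / 2.0
        w = np.clip((pole_width + ramp - d) / ramp, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)
        w = np.where(d <= pole_width, 1.0, w)
    else:
        w = np.where(d <= pole_width + 1e-12, 1.0, 0.0)
    full = np.concatenate([w, w[:n - half][::-1]])
    return CompetenceMask(grid=grid, pole_width=pole_width, soft=soft,
                          weights=full)


def hh_level_at(schedule: HhSchedule, t: float) -> float:
    """Extracellular Hh level at time ``t`` (hpf); piecewise constant.

    Override intervals are half-open ``[t_start, t_end)`` so that the
    wash-out boundary itself already sees the restored baseline.
    """
    for t0, t1, level in schedule.intervals:
        if t0 <= t < t1:
            return level
    return schedule.baseline_level


def profile_to_text(positions: Sequence[float], values: Sequence[float],
                    name: str, units: str = "a.u.") -> str:
    """Two-column tab-separated serialisation with a one-line '#' header."""
    lines = [f"# {name}\tposition (fraction of axis) vs value ({units})"]
    for x, v in zip(positions, values):
        lines.append(f"{x:.17g}\t{v:.17g}")
    return "\n".join(lines) + "\n"
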