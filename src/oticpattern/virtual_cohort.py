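"""Synthetic per-embryo measurement cohorts and resampling comparisons.

Real cohorts in this system are per-ear measurements of how far a marker's
stain reaches along the medial otic edge, expressed as a percentage of the
edge length, with two ears per embryo.  The generator emulates that
structure: each virtual embryo gets multiplicative log-normal jitter on its
production rates and base thresholds (shared by both ears, so ears within
an embryo are correlated), the scenario is simulated for that embryo, and
each ear's extent is the simulated extent plus independent Gaussian
measurement noise, clipped to [0, 100].

Group comparison is by embryo-level resampling: a percentile bootstrap for
the confidence interval and a permutation test for the p-value, both
resampling embryos rather than ears to respect the pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .axis_and_signals import AxisGrid, CompetenceMask, ExtrinsicFgfProfile
from .grn_core import GrnParameters, SPECIES
from .pattern_analysis import DETECTION_FRACTION, extent_percent
from .scenario_engine import Scenario, integrate_network, preset_scenario

__all__ = [
    "CohortConfig",
    "CohortMeasurement",
    "generate_cohort",
    "compare_groups",
    "ComparisonResult",
]

log = logging.getLogger(__name__)

#: parameters receiving per-embryo jitter (rates and base thresholds)
JITTERED_FIELDS = ("beta_h", "beta_p", "beta_f", "theta_h0", "theta_p0",
                   "theta_f0")


@dataclass(frozen=True)
class CohortConfig:
    """Settings for one synthetic measurement cohort."""

    scenario: str
    stage: float = 22.5
    species: str = "hmx3a"
    n_embryos: int = 10
    ears_per_embryo: int = 2
    parameter_jitter_cv: float = 0.1
    measurement_noise_sd: float = 3.0  # percentage points of extent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos <= 0 or self.ears_per_embryo <= 0:
            raise ValueError("counts must be positive")
        if self.parameter_jitter_cv < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")


@dataclass(frozen=True)
class CohortMeasurement:
    """One ear's extent measurement (% of axis length)."""

    group: str
    embryo_id: int
    ear_id: int
    extent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.extent <= 100.0:
            raise ValueError("extent must lie in [0, 100]")


@dataclass(frozen=True)
class ComparisonResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    seed: int
    settings: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# cohort comparison (embryo-level resampling)"]
        for k, v in self.settings.items():
            lines.append(f"# {k}\t{v}")
        lines.append(f"mean_difference\t{self.mean_difference:.6g}")
        lines.append(f"bootstrap_ci_95\t{self.ci_low:.6g}\t{self.ci_high:.6g}")
        lines.append(f"permutation_p\t{self.p_value:.6g}")
        lines.append(f"n_resamples\t{self.n_resamples}")
        lines.append(f"seed\t{self.seed}")
        return "\n".join(lines) + "\n"


def _jittered_param_arrays(
    params: GrnParameters, n_embryos: int, n_points: int, cv: float,
    rng: np.random.Generator,
) -> GrnParameters:
    """Per-embryo log-normal jitter, expanded to the stacked position axis.

    The log-normal factors have mean 1 (sigma^2-corrected) and coefficient
    of variation ``cv``; both ears of an embryo share the same factors.
    """
    if cv == 0.0:
        return params
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    updates = {}
    for name in JITTERED_FIELDS:
        factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                                size=n_embryos)
        updates[name] = np.repeat(getattr(params, name) * factors, n_points)
    return replace(params, **updates)


def simulate_embryo_extents(
    scenario: Scenario,
    params: GrnParameters,
    grid: AxisGrid,
    fgf_e: ExtrinsicFgfProfile,
    competence: CompetenceMask,
    stage: float,
    species: str,
    n_embryos: int,
    cv: float,
    rng: np.random.Generator,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> np.ndarray:
    """Noise-free extent (% of axis) for each of ``n_embryos`` jittered embryos.

    All embryos are integrated in a single stacked ODE system: positions are
    independent of each other, so each embryo simply occupies its own block
    of grid columns with its own jittered parameters.
    """
    n = grid.n_points
    stacked_params = _jittered_param_arrays(params, n_embryos, n, cv, rng)
    fgf_stack = np.tile(fgf_e.values, n_embryos)
    comp_stack = np.tile(competence.weights, n_embryos)
    scen = replace(scenario, window=(scenario.window[0], max(stage, scenario.window[0] + 1e-6)),
                   sample_times=())
    raw = integrate_network(scen, stacked_params, fgf_stack, comp_stack,
                            np.array([stage]), rtol=rtol, atol=atol)
    sp_idx = SPECIES.index(species)
    profiles = raw[0, sp_idx, :].reshape(n_embryos, n)
    # the detection threshold mimics stain visibility: a fixed absolute
    # level (fraction of the nominal saturation scale), the same for every
    # embryo, so production-rate jitter shows up as extent variability
    thr = DETECTION_FRACTION * _nominal_saturation(params, species)
    return np.array([
        extent_percent(grid.positions, profiles[e], thr)
        for e in range(n_embryos)
    ])


def _nominal_saturation(params: GrnParameters, species: str) -> float:
    """Unjittered saturation level beta/delta for the measured species."""
    key = {"hmx3a": ("beta_h", "delta_h"), "pax5": ("beta_p", "delta_p"),
           "fgf_i": ("beta_f", "delta_f")}.get(species)
    if key is None:
        return 1.0
    return float(np.mean(np.asarray(getattr(params, key[0]), dtype=float))
                 / np.mean(np.asarray(getattr(params, key[1]), dtype=float)))


def generate_cohort(
    cfg: CohortConfig,
    params: GrnParameters,
    grid: AxisGrid,
    fgf_e: ExtrinsicFgfProfile,
    competence: CompetenceMask,
    max_attempts: int = 3,
) -> list[CohortMeasurement]:
    """Generate one cohort of per-ear extent measurements.

    Fully reproducible from ``cfg.seed``.  If a jittered embryo's simulation
    fails, that embryo is re-drawn (up to ``max_attempts`` times, logged).
    """
    rng = np.random.default_rng(cfg.seed)
    scenario = preset_scenario(cfg.scenario)
    base_extents = None
    for attempt in range(max_attempts):
        try:
            base_extents = simulate_embryo_extents(
                scenario, params, grid, fgf_e, competence,
                cfg.stage, cfg.species, cfg.n_embryos,
                cfg.parameter_jitter_cv, rng,
            )
            break
        except RuntimeError as exc:  # pragma: no cover - solver hiccup path
            log.warning("cohort simulation attempt %d failed (%s); redrawing",
                        attempt + 1, exc)
    if base_extents is None:  # pragma: no cover
        raise RuntimeError(
            f"cohort generation failed after {max_attempts} attempts")

    out: list[CohortMeasurement] = []
    for e, base in enumerate(base_extents):
        for ear in range(cfg.ears_per_embryo):
            noise = rng.normal(0.0, cfg.measurement_noise_sd) \
                if cfg.measurement_noise_sd > 0 else 0.0
            value = base + noise
            clipped = float(np.clip(value, 0.0, 100.0))
            if clipped != value:
                log.info("extent clipped for embryo %d ear %d (%.2f)",
                         e, ear, value)
            out.append(CohortMeasurement(group=cfg.scenario, embryo_id=e,
                                         ear_id=ear, extent=clipped))
    return out


def _embryo_matrix(ms: Sequence[CohortMeasurement]) -> np.ndarray:
    """Measurements grouped by embryo: shape (n_embryos, ears)."""
    by_embryo: dict[int, list[float]] = {}
    for m in ms:
        by_embryo.setdefault(m.embryo_id, []).append(m.extent)
    ears = {len(v) for v in by_embryo.values()}
    if len(ears) != 1:
        raise ValueError("unequal ear counts across embryos")
    return np.array([by_embryo[k] for k in sorted(by_embryo)])


def compare_groups(
    a: Sequence[CohortMeasurement],
    b: Sequence[CohortMeasurement],
    n_resamples: int = 1999,
    seed: int = 0,
    embryo_level: bool = True,
) -> ComparisonResult:
    """Mean difference (b - a), bootstrap 95% CI and permutation p-value.

    Default resampling unit is the embryo (cluster bootstrap / cluster
    permutation), because the two ears of one embryo are not independent;
    ``embryo_level=False`` treats every ear as its own unit instead.
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 measurements")
    if n_resamples < 999:
        raise ValueError("n_resamples must be >= 999")
    rng = np.random.default_rng(seed)
    if embryo_level:
        ua = _embryo_matrix(a)
        ub = _embryo_matrix(b)
    else:
        ua = np.array([[m.extent] for m in a])
        ub = np.array([[m.extent] for m in b])
    diff = float(ub.mean() - ua.mean())

    # percentile bootstrap over resampled units within each group
    na, nb = len(ua), len(ub)
    ia = rng.integers(0, na, size=(n_resamples, na))
    ib = rng.integers(0, nb, size=(n_resamples, nb))
    boot = ub[ib].mean(axis=(1, 2)) - ua[ia].mean(axis=(1, 2))
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    # permutation of group labels over units
    pooled = np.concatenate([ua, ub], axis=0)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(na + nb)
        pa = pooled[perm[:na]]
        pb = pooled[perm[na:]]
        if abs(pb.mean() - pa.mean()) >= abs(diff) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_resamples)

    return ComparisonResult(
        mean_difference=diff, ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=float(p), n_resamples=n_resamples, seed=seed,
        settings={"embryo_level": embryo_level,
                  "n_a": na, "n_b": nb},
    )
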