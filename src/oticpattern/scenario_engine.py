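"""Experimental regimes as event schedules, and model integration through them.

A :class:`Scenario` bundles everything that distinguishes one experimental
regime from another: the Hh input schedule, heat-shock transgene pulses,
the *hmx3a* loss-of-function flag, the simulation window and assay stages.
The integrator splits the time axis at every event discontinuity (pulse
edges, Hh override boundaries) so the ODE solver never steps across one.

Presets encode the regimes used to probe anteroposterior duplication:
transient systemic *fgf3* mis-expression (heat shock at 14 or 18 hpf),
cyclopamine inhibition of Hh signalling from 14–22.5 hpf with wash-out,
constitutive *smoothened* loss, and *hmx3a* loss/gain of function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .axis_and_signals import (
    AxisGrid,
    CompetenceMask,
    ExtrinsicFgfProfile,
    HhSchedule,
    hh_level_at,
)
from .grn_core import GrnParameters, N_SPECIES, SPECIES, rhs

__all__ = [
    "Scenario",
    "Kymograph",
    "PRESET_NAMES",
    "preset_scenario",
    "simulate",
    "sample_stage",
]

#: wild-type extracellular Hh level (a.u.)
HH_BASELINE = 1.0
#: residual Hh during cyclopamine treatment, as the pathway target gene is
#: down-regulated but not abolished under the drug
CYCLOPAMINE_FRACTION = 0.2
#: heat shock: 30 min at 39C plus the 30 min step-down at 33C are treated
#: as ~1 h of elevated transgene production
HS_PULSE_DURATION = 1.0
#: transgene production amplitude (a.u./h), calibrated so that total Fgf
#: exceeds every effective threshold axis-wide during the pulse
HS_PULSE_AMPLITUDE = 20.0

T_START = 11.5   # hpf; onset stage of the earliest anterior marker
T_END = 36.0     # hpf; latest modelled assay stage
DEFAULT_SAMPLE_TIMES = (16.0, 22.5, 25.5, 30.0, 36.0)
KYMO_DT = 0.25   # h; fine sampling interval for kymographs

PRESET_NAMES = (
    "wild_type",
    "fgf3_hs_14",
    "fgf3_hs_18",
    "cyclopamine_14_22.5",
    "smo_mutant",
    "hmx3a_lof",
    "hmx3a_hs_14",
)


@dataclass(frozen=True)
class Scenario:
    """A perturbation schedule for one in-silico experiment."""

    name: str
    hh_schedule: HhSchedule
    pulses: tuple = ()  # (species in {fgf3, hmx3a}, start hpf, duration h, amplitude)
    hmx3a_lof: bool = False
    window: tuple[float, float] = (T_START, T_END)
    sample_times: tuple = DEFAULT_SAMPLE_TIMES

    def __post_init__(self) -> None:
        t0, t1 = self.window
        if not t1 > t0:
            raise ValueError("scenario window must be non-empty")
        pulses = tuple(
            (str(sp), float(s), float(d), float(a)) for sp, s, d, a in self.pulses
        )
        for sp, start, dur, amp in pulses:
            if sp not in ("fgf3", "hmx3a"):
                raise ValueError(f"unknown pulse species {sp!r}")
            if dur <= 0 or amp < 0:
                raise ValueError("pulse duration must be > 0 and amplitude >= 0")
            if start < t0 or start + dur > t1:
                raise ValueError(
                    f"pulse [{start}, {start + dur}] lies outside the "
                    f"simulation window [{t0}, {t1}]"
                )
        st = tuple(sorted(float(t) for t in self.sample_times))
        if st and (st[0] < t0 or st[-1] > t1):
            raise ValueError("sample_times must lie within the window")
        object.__setattr__(self, "pulses", pulses)
        object.__setattr__(self, "sample_times", st)

    def breakpoints(self) -> list[float]:
        """Event discontinuities inside the window, sorted and unique."""
        t0, t1 = self.window
        pts = {t0, t1}
        for _, start, dur, _ in self.pulses:
            pts.update((start, start + dur))
        for b in self.hh_schedule.boundaries():
            if t0 < b < t1:
                pts.add(b)
        return sorted(pts)

    def pulse_rates(self, t: float) -> tuple[float, float]:
        """Instantaneous transgene production rates (fgf3, hmx3a) at ``t``."""
        rf = rh = 0.0
        for sp, start, dur, amp in self.pulses:
            if start <= t < start + dur:
                if sp == "fgf3":
                    rf += amp
                else:
                    rh += amp
        return rf, rh


@dataclass(frozen=True)
class Kymograph:
    """Simulated expression of one species over time and axis position."""

    species: str
    times: np.ndarray
    positions: np.ndarray
    values: np.ndarray  # shape (n_times, n_positions)
    scenario: str = ""
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (t.size, x.size):
            raise ValueError(
                f"kymograph matrix shape {v.shape} inconsistent with "
                f"{t.size} times x {x.size} positions"
            )
        if np.any(v < 0):
            raise ValueError("kymograph values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "values", v)


def preset_scenario(name: str) -> Scenario:
    """Return a fully populated preset scenario by name."""
    wt_hh = HhSchedule(baseline_level=HH_BASELINE)
    if name == "wild_type":
        return Scenario(name=name, hh_schedule=wt_hh)
    if name == "fgf3_hs_14":
        return Scenario(name=name, hh_schedule=wt_hh,
                        pulses=(("fgf3", 14.0, HS_PULSE_DURATION,
                                 HS_PULSE_AMPLITUDE),))
    if name == "fgf3_hs_18":
        return Scenario(name=name, hh_schedule=wt_hh,
                        pulses=(("fgf3", 18.0, HS_PULSE_DURATION,
                                 HS_PULSE_AMPLITUDE),))
    if name == "cyclopamine_14_22.5":
        sched = HhSchedule(
            baseline_level=HH_BASELINE,
            intervals=((14.0, 22.5, CYCLOPAMINE_FRACTION * HH_BASELINE),),
        )
        return Scenario(name=name, hh_schedule=sched)
    if name == "smo_mutant":
        return Scenario(name=name, hh_schedule=HhSchedule(baseline_level=0.0))
    if name == "hmx3a_lof":
        return Scenario(name=name, hh_schedule=wt_hh, hmx3a_lof=True)
    if name == "hmx3a_hs_14":
        return Scenario(name=name, hh_schedule=wt_hh,
                        pulses=(("hmx3a", 14.0, HS_PULSE_DURATION,
                                 HS_PULSE_AMPLITUDE),))
    raise ValueError(
        f"unknown scenario {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
    )


def integrate_network(
    scenario: Scenario,
    params: GrnParameters,
    fgf_e_values: np.ndarray,
    competence: np.ndarray,
    t_eval: np.ndarray,
    rtol: float = 1e-7,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the network over the scenario window on raw arrays.

    Returns the state sampled at ``t_eval`` (which must be sorted and lie in
    the window), shape ``(len(t_eval), N_SPECIES, n_positions)``.  The Hh
    effector starts at equilibrium with the extracellular level at the window
    start; all other species start at zero.  Integration restarts at every
    event discontinuity.  Deterministic; no randomness anywhere.
    """
    t0, t1 = scenario.window
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval[0] < t0 - 1e-9 or t_eval[-1] > t1 + 1e-9):
        raise ValueError("t_eval must lie within the scenario window")
    n = fgf_e_values.shape[0]
    if competence.shape[0] != n:
        raise ValueError("competence and Fgf profile grids differ")

    y = np.zeros(N_SPECIES * n)
    y[6 * n:] = hh_level_at(scenario.hh_schedule, t0)  # effector equilibrated

    out = np.empty((t_eval.size, N_SPECIES * n))
    segs = scenario.breakpoints()
    for a, b in zip(segs, segs[1:]):
        mid = 0.5 * (a + b)
        hh = hh_level_at(scenario.hh_schedule, mid)
        rate_f, rate_h = scenario.pulse_rates(mid)
        mask = (t_eval >= a - 1e-9) & (t_eval <= b + 1e-9) if a > segs[0] \
            else (t_eval <= b + 1e-9)
        seg_eval = t_eval[mask]
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
            t_eval=np.unique(np.concatenate([seg_eval, [b]])),
            args=(params, fgf_e_values, competence, hh, rate_f, rate_h,
                  scenario.hmx3a_lof),
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed in segment [{a}, {b}] of scenario "
                f"{scenario.name!r}: {sol.message}"
            )
        y = sol.y[:, -1]
        if seg_eval.size:
            # map each requested time to its column in this segment's output
            idx = np.searchsorted(sol.t, seg_eval)
            idx = np.clip(idx, 0, sol.t.size - 1)
            out[mask] = sol.y[:, idx].T
    low = out.min()
    if low < -1e-9:
        raise RuntimeError(
            f"trajectory violated non-negativity (min {low:.3e})"
        )
    return np.clip(out, 0.0, None).reshape(t_eval.size, N_SPECIES, n)


def simulate(
    scenario: Scenario,
    params: GrnParameters,
    grid: AxisGrid,
    fgf_e: ExtrinsicFgfProfile,
    competence: CompetenceMask,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    kymo_dt: float = KYMO_DT,
) -> dict[str, Kymograph]:
    """Run one scenario and return a kymograph per species.

    Sampling times are a uniform ``kymo_dt`` grid over the window, augmented
    with the scenario's assay stages and event boundaries.
    """
    if fgf_e.grid.n_points != grid.n_points or competence.grid.n_points != grid.n_points:
        raise ValueError("gradient, competence and grid sizes must agree")
    t0, t1 = scenario.window
    times = np.arange(t0, t1 + 1e-9, kymo_dt)
    times = np.unique(np.concatenate(
        [times, scenario.sample_times, scenario.breakpoints(), [t1]]))
    raw = integrate_network(
        scenario, params, fgf_e.values, competence.weights, times,
        rtol=rtol, atol=atol,
    )
    meta = {"scenario": scenario.name, "units": "a.u.",
            "n_points": str(grid.n_points)}
    return {
        sp: Kymograph(species=sp, times=times, positions=grid.positions,
                      values=raw[:, i, :], scenario=scenario.name, meta=meta)
        for i, sp in enumerate(SPECIES)
    }


def sample_stage(kymo: Kymograph, t: float) -> tuple[np.ndarray, float]:
    """Profile at the stored time nearest ``t``; returns (profile, actual t)."""
    if t < kymo.times[0] - 1e-9 or t > kymo.times[-1] + 1e-9:
        raise ValueError(
            f"t={t} outside kymograph range [{kymo.times[0]}, {kymo.times[-1]}]"
        )
    i = int(np.argmin(np.abs(kymo.times - t)))
    return kymo.values[i].copy(), float(kymo.times[i])
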