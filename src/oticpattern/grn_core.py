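"""Gene-regulatory-network core for otic anteroposterior patterning.

State per axis position (all arbitrary units, a.u.):

====== =====================================================================
``h``    *hmx3a* mRNA — earliest anterior marker, autoregulatory
``p``    *pax5* mRNA — anterior marker requiring both Fgf and Hmx3a input
``f_i``  intrinsic *fgf* mRNA — pole-restricted local Fgf source
``f_x``  exogenous *fgf3* transgene mRNA (heat-shock pulse)
``h_x``  exogenous *hmx3a* transgene mRNA (heat-shock pulse)
``P_f``  locally produced Fgf protein (translated from ``f_i`` + ``f_x``)
``G``    intracellular Hh effector, relaxing toward extracellular Hh
====== =====================================================================

Regulatory logic: *hmx3a* integrates Fgf and its own protein as a summed
(OR-like) input, so autoregulation alone can maintain expression after a
transient Fgf pulse decays; *pax5* and intrinsic *fgf* require Fgf AND
Hmx3a activity (product of Hill terms), with intrinsic *fgf* additionally
gated by pole competence.  Hh raises every Fgf-response threshold linearly
through the effector ``G``: ``theta_eff = theta0 * (1 + alpha * G)``.

Concentrations are normalised so that ``beta/delta = 1`` for each mRNA
(saturation level 1 a.u.); time is in hours post fertilisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "GrnParameters",
    "ModelState",
    "hill_activation",
    "effective_threshold",
    "total_fgf",
    "hmx3a_activity",
    "rhs",
    "single_cell_steady_state",
]

SPECIES = ("hmx3a", "pax5", "fgf_i", "fgf_x", "hmx_x", "P_f", "G")
N_SPECIES = len(SPECIES)


@dataclass(frozen=True)
class GrnParameters:
    """Kinetic parameters of the otic anterior network.

    Rates in a.u./h or 1/h; thresholds in a.u.; weights dimensionless.
    Any field may also be a numpy array broadcastable over axis positions
    (used by the virtual-cohort generator to stack jittered embryos).
    """

    # maximal mRNA production rates (a.u./h)
    beta_h: float = 0.5
    beta_p: float = 0.7
    beta_f: float = 0.7
    # mRNA decay rates (1/h); beta/delta = 1 sets the saturation scale
    delta_h: float = 0.5
    delta_p: float = 0.7
    delta_f: float = 0.7
    # base Fgf-response thresholds (a.u.) at zero Hh effector
    theta_h0: float = 0.2
    theta_p0: float = 0.17
    theta_f0: float = 0.10
    # Hh threshold-boost coefficients (per a.u. of effector G)
    alpha_h: float = 9.0
    alpha_p: float = 4.0
    alpha_f: float = 7.0
    # Hmx3a input
    w_auto: float = 4.4          # autoregulation weight into the hmx3a gate
    theta_hm: float = 0.3        # Hmx3a-activity threshold in the AND gates
    w_hm_p: float = 1.0          # Hmx3a input weights into pax5 / fgf_i
    w_hm_f: float = 1.0
    # Hill steepness
    n_hill: float = 2.0
    # Fgf protein pool
    k_translate: float = 1.8     # protein production per unit fgf mRNA (1/h)
    delta_P: float = 1.0         # Fgf protein decay (1/h)
    # Hh effector relaxation rate (1/h); default half-life ~4 h
    delta_G: float = 0.1733
    # exogenous transgene mRNA decay (1/h)
    delta_x: float = 0.7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = np.asarray(getattr(self, f.name), dtype=float)
            if np.any(v < 0):
                raise ValueError(f"parameter {f.name} must be >= 0")
            if f.name.startswith("delta") and np.any(v <= 0):
                raise ValueError(f"decay rate {f.name} must be > 0")
        if np.any(np.asarray(self.n_hill) < 1):
            raise ValueError("n_hill must be >= 1")

    def with_updates(self, **kwargs) -> "GrnParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> Mapping[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ModelState:
    """Per-position concentrations of the seven network species."""

    h: np.ndarray
    p: np.ndarray
    f_i: np.ndarray
    f_x: np.ndarray
    h_x: np.ndarray
    P_f: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.h)
        for f in fields(self):
            arr = np.asarray(getattr(self, f.name), dtype=float)
            if arr.shape != (n,):
                raise ValueError("all species vectors must share the grid size")
            setattr(self, f.name, arr)

    @classmethod
    def zeros(cls, n: int, G0: float = 0.0) -> "ModelState":
        z = lambda: np.zeros(n)  # noqa: E731
        return cls(h=z(), p=z(), f_i=z(), f_x=z(), h_x=z(), P_f=z(),
                   G=np.full(n, float(G0)))

    @classmethod
    def from_flat(cls, y: np.ndarray, n: int) -> "ModelState":
        m = y.reshape(N_SPECIES, n)
        return cls(*m)

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.h, self.p, self.f_i, self.f_x,
                               self.h_x, self.P_f, self.G])


def hill_activation(s, theta, n):
    """Activating Hill function ``s^n / (s^n + theta^n)`` in [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("Hill threshold theta must be > 0")
    if np.any(np.asarray(n) < 1):
        raise ValueError("Hill coefficient n must be >= 1")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("Hill input signal must be >= 0")
    r = (s / theta) ** n
    return r / (1.0 + r)


def effective_threshold(theta0, alpha, G):
    """Hh-modulated threshold ``theta0 * (1 + alpha * G)``."""
    theta0 = np.asarray(theta0, dtype=float)
    if np.any(theta0 <= 0):
        raise ValueError("base threshold theta0 must be > 0")
    if np.any(np.asarray(alpha) < 0) or np.any(np.asarray(G) < 0):
        raise ValueError("alpha and G must be >= 0")
    return theta0 * (1.0 + np.asarray(alpha, float) * np.asarray(G, float))


def total_fgf(state: ModelState, fgf_e_values: np.ndarray) -> np.ndarray:
    """Total Fgf protein signal: extrinsic gradient + local protein pool.

    Transgene-derived *fgf3* mRNA feeds the same local protein pool ``P_f``
    (translated together with intrinsic *fgf*), so the sum of the two terms
    already covers all three sources.
    """
    fgf_e_values = np.asarray(fgf_e_values, dtype=float)
    if fgf_e_values.shape != state.P_f.shape:
        raise ValueError("extrinsic Fgf profile does not match state grid size")
    return fgf_e_values + state.P_f


def hmx3a_activity(state: ModelState, lof: bool = False) -> np.ndarray:
    """Effective Hmx3a protein activity.

    Endogenous and transgene-derived mRNA contribute additively; under the
    homeodomain-truncating loss-of-function allele the protein is inert, so
    activity is zero regardless of mRNA levels.
    """
    if lof:
        return np.zeros_like(state.h)
    return state.h + state.h_x


def rhs(
    t: float,
    y: np.ndarray,
    params: GrnParameters,
    fgf_e_values: np.ndarray,
    competence: np.ndarray,
    hh_level: float,
    pulse_fgf_rate: float = 0.0,
    pulse_hmx_rate: float = 0.0,
    hmx3a_lof: bool = False,
) -> np.ndarray:
    """Time derivative of the flattened state vector.

    ``hh_level`` and the pulse production rates are the *instantaneous*
    values at ``t``; the scenario engine splits integration at every
    discontinuity so they are constant within a solver call.
    """
    n = fgf_e_values.shape[0]
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y.reshape(N_SPECIES, n)))
        sp, pos = bad[0]
        raise FloatingPointError(
            f"non-finite state for species {SPECIES[sp]} at grid index {pos}"
        )
    state = ModelState.from_flat(np.maximum(y, 0.0), n)
    pr = params

    F = total_fgf(state, fgf_e_values)
    hmx = hmx3a_activity(state, lof=hmx3a_lof)
    hill_hm_p = hill_activation(pr.w_hm_p * hmx, pr.theta_hm, pr.n_hill)
    hill_hm_f = hill_activation(pr.w_hm_f * hmx, pr.theta_hm, pr.n_hill)

    th_h = effective_threshold(pr.theta_h0, pr.alpha_h, state.G)
    th_p = effective_threshold(pr.theta_p0, pr.alpha_p, state.G)
    th_f = effective_threshold(pr.theta_f0, pr.alpha_f, state.G)

    dh = pr.beta_h * hill_activation(F + pr.w_auto * hmx, th_h, pr.n_hill) \
        - pr.delta_h * state.h
    dp = pr.beta_p * hill_activation(F, th_p, pr.n_hill) * hill_hm_p \
        - pr.delta_p * state.p
    df_i = pr.beta_f * competence \
        * hill_activation(F, th_f, pr.n_hill) * hill_hm_f \
        - pr.delta_f * state.f_i
    df_x = pulse_fgf_rate - pr.delta_x * state.f_x
    dh_x = pulse_hmx_rate - pr.delta_x * state.h_x
    dP_f = pr.k_translate * (state.f_i + state.f_x) - pr.delta_P * state.P_f
    dG = pr.delta_G * (hh_level - state.G)

    return np.concatenate([dh, dp, df_i, df_x, dh_x, dP_f, dG])


def single_cell_steady_state(
    F: float,
    G: float,
    competent: bool,
    params: GrnParameters,
    hmx3a_lof: bool = False,
    h_init: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 20000,
    damping: float = 0.25,
) -> ModelState:
    """Equilibrium of a single cell at fixed total-Fgf input ``F`` and
    effector level ``G``, by damped fixed-point iteration.

    ``F`` is held fixed as the *external* Fgf input; the cell's own protein
    pool (from intrinsic/exogenous *fgf* mRNA) is added on top, so the local
    positive feedback loop is part of the solved system.  ``h_init`` selects
    the basin of attraction when the *hmx3a* equation is bistable.

    Raises ``RuntimeError`` with the last residual if the iteration fails to
    converge.
    """
    pr = params
    c = 1.0 if competent else 0.0
    h = float(h_init)
    p = f_i = P_f = 0.0
    last_res = np.inf
    for _ in range(max_iter):
        hmx = 0.0 if hmx3a_lof else h
        F_tot = F + P_f
        th_h = effective_threshold(pr.theta_h0, pr.alpha_h, G)
        th_p = effective_threshold(pr.theta_p0, pr.alpha_p, G)
        th_f = effective_threshold(pr.theta_f0, pr.alpha_f, G)
        h_new = pr.beta_h / pr.delta_h * hill_activation(
            F_tot + pr.w_auto * hmx, th_h, pr.n_hill)
        p_new = pr.beta_p / pr.delta_p * hill_activation(F_tot, th_p, pr.n_hill) \
            * hill_activation(pr.w_hm_p * hmx, pr.theta_hm, pr.n_hill)
        f_new = pr.beta_f / pr.delta_f * c * hill_activation(F_tot, th_f, pr.n_hill) \
            * hill_activation(pr.w_hm_f * hmx, pr.theta_hm, pr.n_hill)
        P_new = pr.k_translate / pr.delta_P * f_i
        last_res = max(abs(h_new - h), abs(p_new - p),
                       abs(f_new - f_i), abs(P_new - P_f))
        h += damping * (h_new - h)
        p += damping * (p_new - p)
        f_i += damping * (f_new - f_i)
        P_f += damping * (P_new - P_f)
        if last_res < tol:
            break
    else:
        raise RuntimeError(
            f"single-cell steady state did not converge; last residual {last_res:.3e}"
        )
    one = np.ones(1)
    return ModelState(h=h * one, p=p * one, f_i=f_i * one,
                      f_x=0.0 * one, h_x=0.0 * one, P_f=P_f * one,
                      G=float(G) * one)
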