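import numpy as np
import pytest

from oticpattern import (
    GrnParameters,
    ModelState,
    effective_threshold,
    hill_activation,
    hmx3a_activity,
    rhs,
    single_cell_steady_state,
    total_fgf,
)
from oticpattern.grn_core import N_SPECIES


class TestHillActivation:
    @pytest.mark.parametrize(
        "s, theta, n, expected",
        [
            (1.0, 1.0, 2.0, 0.5),        # midpoint
            (0.0, 1.0, 2.0, 0.0),        # zero input
            (2.0, 1.0, 4.0, 16.0 / 17.0),
        ],
    )
    def test_values(self, s, theta, n, expected):
        assert hill_activation(s, theta, n) == pytest.approx(expected)

    def test_monotone_in_signal_and_threshold(self):
        s = np.linspace(0, 5, 50)
        v = hill_activation(s, 1.0, 2.0)
        assert np.all(np.diff(v) > 0)
        assert hill_activation(1.0, 2.0, 2.0) < hill_activation(1.0, 0.5, 2.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(1.0, 0.0, 2.0)


class TestEffectiveThreshold:
    def test_linear_boost(self):
        assert effective_threshold(1.0, 1.0, 1.0) == 2.0
        assert effective_threshold(0.7, 3.0, 0.0) == 0.7
        base = effective_threshold(1.0, 2.0, 1.0) - 1.0
        doubled = effective_threshold(1.0, 2.0, 2.0) - 1.0
        assert doubled == pytest.approx(2 * base)


class TestInputAssembly:
    def test_total_fgf_reduces_to_extrinsic_for_zero_state(self, fgf_e):
        state = ModelState.zeros(fgf_e.values.size)
        assert np.array_equal(total_fgf(state, fgf_e.values), fgf_e.values)

    def test_total_fgf_adds_local_protein(self):
        state = ModelState.zeros(11)
        state.P_f[:] = 1.0
        assert np.all(total_fgf(state, np.full(11, 2.0)) == 3.0)

    def test_total_fgf_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_fgf(ModelState.zeros(11), np.zeros(12))

    def test_hmx3a_activity_sums_endogenous_and_transgene(self):
        state = ModelState.zeros(11)
        state.h[:] = 1.0
        state.h_x[:] = 0.5
        assert np.all(hmx3a_activity(state) == 1.5)
        assert np.all(hmx3a_activity(state, lof=True) == 0.0)


class TestRhs:
    def _derivs(self, state, params, fgf, comp, hh, **kw):
        n = fgf.size
        d = rhs(0.0, state.to_flat(), params, fgf, comp, hh, **kw)
        return d.reshape(N_SPECIES, n)

    def test_zero_state_zero_fgf_only_effector_moves(self, params):
        n = 11
        state = ModelState.zeros(n)
        fgf = np.zeros(n)
        comp = np.ones(n)
        d = self._derivs(state, params, fgf, comp, hh=1.0)
        assert np.all(d[:6] == 0.0)   # no input, no production, no decay
        assert np.all(d[6] > 0.0)     # effector relaxes up toward Hh level

    def test_plateau_fgf_drives_hmx3a_on(self, params, fgf_e, competence):
        n = fgf_e.values.size
        state = ModelState.zeros(n, G0=1.0)
        d = self._derivs(state, params, fgf_e.values, competence.weights, 1.0)
        assert d[0][0] > 0.0  # anterior-most position, hmx3a production

    def test_transgene_pulse_cannot_induce_fgf_i_off_the_poles(
        self, params, fgf_e, competence
    ):
        n = fgf_e.values.size
        state = ModelState.zeros(n, G0=1.0)
        state.f_x[:] = 10.0  # uniform exogenous fgf3 mRNA
        state.P_f[:] = 10.0
        state.h[:] = 0.5
        d = self._derivs(state, params, fgf_e.values, competence.weights, 1.0)
        mid = np.abs(fgf_e.grid.positions - 0.5) < 0.2
        assert np.all(d[0][mid] > 0.0)                      # hmx3a induced
        assert np.all(d[2][mid] == 0.0)                     # fgf_i gated off
        assert d[2][0] > 0.0                                # but on at pole

    def test_non_finite_state_rejected_with_location(self, params):
        n = 11
        y = ModelState.zeros(n).to_flat()
        y[2 * n + 3] = np.nan  # fgf_i at grid index 3
        with pytest.raises(FloatingPointError, match="fgf_i.*index 3"):
            rhs(0.0, y, params, np.zeros(n), np.ones(n), 1.0)


class TestSteadyState:
    def test_no_input_gives_empty_equilibrium(self, params):
        ss = single_cell_steady_state(F=0.0, G=1.0, competent=True, params=params)
        assert ss.h[0] == pytest.approx(0.0, abs=1e-8)
        assert ss.p[0] == pytest.approx(0.0, abs=1e-8)

    def test_saturating_input_reaches_closed_form_limits(self, params):
        ss = single_cell_steady_state(F=200.0, G=0.0, competent=True, params=params)
        h_max = params.beta_h / params.delta_h
        assert ss.h[0] == pytest.approx(h_max, rel=0.01)
        # pax5 saturates in Fgf; its Hmx gate sits at the finite hmx3a level
        p_expected = params.beta_p / params.delta_p * float(
            hill_activation(params.w_hm_p * h_max, params.theta_hm, params.n_hill)
        )
        assert ss.p[0] == pytest.approx(p_expected, rel=0.01)

    def test_autoregulation_bistability_against_root_scan(self, params):
        """At intermediate Fgf the scalar hmx3a equation has two stable
        fixed points; brute-force root scan is the oracle.  A non-competent
        cell is used so no local fgf feedback perturbs the scalar equation."""
        F, G = 0.15, 1.0
        theta = effective_threshold(params.theta_h0, params.alpha_h, G)
        h_grid = np.linspace(0.0, 1.0, 200001)
        resid = (
            hill_activation(F + params.w_auto * h_grid, theta, params.n_hill)
            * params.beta_h / params.delta_h
            - h_grid
        )
        roots = h_grid[:-1][np.diff(np.sign(resid)) != 0]
        stable = roots[::2]  # sign goes +,-,+ around alternating roots
        assert len(roots) == 3 and len(stable) == 2

        lo = single_cell_steady_state(F, G, False, params, h_init=0.0)
        hi = single_cell_steady_state(F, G, False, params, h_init=1.0)
        assert lo.h[0] == pytest.approx(stable[0], abs=1e-4)
        assert hi.h[0] == pytest.approx(stable[1], abs=1e-4)
        assert hi.h[0] - lo.h[0] > 0.3

    def test_steady_pax5_non_increasing_in_hh_effector(self, params):
        levels = [
            single_cell_steady_state(F=1.0, G=g, competent=False,
                                     params=params, h_init=1.0).p[0]
            for g in np.linspace(0.0, 2.0, 9)
        ]
        assert np.all(np.diff(levels) <= 1e-12)

    def test_loss_of_function_kills_pax5_and_fgf_i(self, params):
        ss = single_cell_steady_state(F=1.0, G=1.0, competent=True,
                                      params=params, hmx3a_lof=True, h_init=1.0)
        assert ss.p[0] == pytest.approx(0.0, abs=1e-8)
        assert ss.f_i[0] == pytest.approx(0.0, abs=1e-8)
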