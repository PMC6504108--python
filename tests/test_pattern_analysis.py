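import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oticpattern import (
    asymmetry_index,
    call_domains,
    extent_percent,
    load_suite,
    run_concordance,
)
from oticpattern.pattern_analysis import (
    ConcordanceAssertion,
    evaluate_assertion,
)


def brute_force_domains(x, v, threshold, min_width):
    """Independent reference: explicit index-by-index scan implementing
    thresholding, one-point dip closing and the width filter."""
    n = len(x)
    above = [v[i] >= threshold for i in range(n)]
    closed = list(above)
    for i in range(1, n - 1):
        if above[i - 1] and above[i + 1] and not above[i]:
            closed[i] = True
    bounds = []
    i = 0
    while i < n:
        if closed[i]:
            j = i
            while j + 1 < n and closed[j + 1]:
                j += 1
            if x[j] - x[i] >= min_width - 1e-12:
                bounds.append((x[i], x[j]))
            i = j + 1
        else:
            i += 1
    return bounds


class TestCallDomains:
    def test_zero_profile_yields_nothing(self):
        x = np.linspace(0, 1, 101)
        assert call_domains(x, np.zeros(101), 0.2) == []

    def test_two_rectangular_pole_bumps(self):
        x = np.linspace(0, 1, 101)
        v = np.where((x <= 0.2) | (x >= 0.8), 1.0, 0.0)
        doms = call_domains(x, v, 0.5)
        assert len(doms) == 2
        assert doms[0].start == 0.0 and doms[0].end == pytest.approx(0.2)
        assert doms[1].start == pytest.approx(0.8) and doms[1].end == 1.0
        assert doms[0].peak_level == doms[0].mean_level == 1.0

    def test_single_point_dip_is_closed(self):
        x = np.linspace(0, 1, 101)
        v = np.ones(101)
        v[50] = 0.0
        assert len(call_domains(x, v, 0.5)) == 1

    def test_narrow_spike_discarded(self):
        x = np.linspace(0, 1, 101)
        v = np.zeros(101)
        v[40:43] = 1.0  # width 0.02 < default min_width 0.05
        assert call_domains(x, v, 0.5) == []

    def test_non_finite_profile_rejected(self):
        x = np.linspace(0, 1, 101)
        v = np.zeros(101)
        v[3] = np.inf
        with pytest.raises(ValueError, match="finite"):
            call_domains(x, v, 0.5)

    def test_agrees_with_brute_force_on_random_profiles(self, rng):
        """1,000 random piecewise-constant profiles, exact agreement."""
        x = np.linspace(0, 1, 101)
        for _ in range(1000):
            n_seg = rng.integers(1, 12)
            edges = np.sort(rng.choice(np.arange(1, 101), n_seg, replace=False))
            levels = rng.uniform(0, 1, n_seg + 1)
            v = np.repeat(levels, np.diff(np.r_[0, edges, 101]))
            doms = call_domains(x, v, 0.5)
            ref = brute_force_domains(x, v, 0.5, 0.05)
            assert [(d.start, d.end) for d in doms] == ref


class TestExtentPercent:
    def test_uniform_profiles(self):
        x = np.linspace(0, 1, 101)
        assert extent_percent(x, np.full(101, 0.9), 0.2) == 100.0
        assert extent_percent(x, np.full(101, 0.1), 0.2) == 0.0

    def test_rectangular_bump_extent(self):
        x = np.linspace(0, 1, 101)
        v = np.where(x <= 0.4, 1.0, 0.0)
        assert extent_percent(x, v, 0.5) == pytest.approx(40.0, abs=1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.lists(st.floats(0.0, 1.0), min_size=11, max_size=60),
        thresholds=st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)),
    )
    def test_threshold_monotonicity(self, data, thresholds):
        """Raising the threshold never increases extent or domain length."""
        x = np.linspace(0, 1, len(data))
        v = np.array(data)
        lo, hi = sorted(thresholds)
        assert extent_percent(x, v, hi) <= extent_percent(x, v, lo) + 1e-9
        spacing = 1.0 / (len(data) - 1)
        len_hi = sum(d.width for d in call_domains(x, v, hi, min_width=spacing))
        len_lo = sum(d.width for d in call_domains(x, v, lo, min_width=spacing))
        assert len_hi <= len_lo + 1e-9

    def test_domain_length_consistent_with_extent(self, rng):
        """Called-domain length never exceeds the interpolated extent by
        more than one grid cell per closure event (closed single-point dips
        are counted as expressing by the domain caller but not by the
        extent measure)."""
        x = np.linspace(0, 1, 101)
        for _ in range(200):
            v = np.abs(np.cumsum(rng.normal(0, 0.2, 101)))
            above = v >= 0.5
            n_dips = int(np.sum(~above[1:-1] & above[:-2] & above[2:]))
            total = sum(d.width for d in call_domains(x, v, 0.5))
            slack = 0.01 * (1 + n_dips)
            assert total <= extent_percent(x, v, 0.5) / 100.0 + slack + 1e-9


class TestAsymmetryIndex:
    def test_symmetric_profile_balances(self):
        x = np.linspace(0, 1, 101)
        v = np.exp(-((x - 0.5) ** 2))
        assert asymmetry_index(x, v) == pytest.approx(0.0, abs=1e-12)

    def test_anterior_only_profile(self):
        x = np.linspace(0, 1, 101)
        assert asymmetry_index(x, np.where(x < 0.5, 1.0, 0.0)) == 1.0

    def test_all_zero_convention(self):
        x = np.linspace(0, 1, 101)
        assert asymmetry_index(x, np.zeros(101)) == 0.0


class TestConcordance:
    def test_empty_suite_is_vacuous_pass(self, all_results):
        report = run_concordance(all_results, [])
        assert report.fraction_passed == 1.0 and report.all_passed

    def test_heat_shock_expansion_assertion_passes(self, all_results):
        a = ConcordanceAssertion(
            id="x", scenario="fgf3_hs_14", species="hmx3a", stage=16.0,
            predicate="extent_ge", argument=95.0)
        measured, ok = evaluate_assertion(a, all_results, threshold=0.2)
        assert ok and measured >= 95.0

    def test_loss_of_function_ratio_assertion_passes(self, all_results):
        a = ConcordanceAssertion(
            id="x", scenario="hmx3a_lof", species="pax5", stage=24.0,
            predicate="level_ratio_le", argument=0.25, ref_scenario="wild_type")
        measured, ok = evaluate_assertion(a, all_results, threshold=0.2)
        assert ok and measured < 0.25

    def test_missing_scenario_named_in_error(self, all_results):
        a = ConcordanceAssertion(
            id="x", scenario="not_there", species="pax5", stage=24.0,
            predicate="extent_ge", argument=1.0)
        with pytest.raises(KeyError, match="not_there"):
            evaluate_assertion(a, all_results, threshold=0.2)

    def test_unknown_predicate_rejected(self):
        with pytest.raises(ValueError, match="predicate"):
            ConcordanceAssertion(id="x", scenario="wild_type", species="pax5",
                                 stage=24.0, predicate="bogus", argument=0.0)

    def test_shipped_suite_structure(self):
        suite = load_suite()
        assert len(suite) >= 12
        covered = {a.scenario for a in suite}
        assert {"wild_type", "fgf3_hs_14", "fgf3_hs_18", "cyclopamine_14_22.5",
                "smo_mutant", "hmx3a_lof"} <= covered
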