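import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from asdscreen import (ChiTemperatureModel, Component,
                       MeltingDepressionDataset, build_phase_diagram, chi_at,
                       chi_from_hsp, classify_state, critical_point,
                       delta_g_mix, depression_transform, fit_chi_at_tm,
                       fit_chi_temperature_model, solubility_boundary_at_T,
                       spinodal_chi, spinodal_composition_at_T, state_point,
                       tg_mixture)
from asdscreen.simulate import SyntheticSpec, simulate_melting_depression


class TestFreeEnergy:
    @pytest.mark.parametrize("phi, m, chi, expected", [
        (0.0, 100.0, 2.0, 0.0),
        (1.0, 100.0, 2.0, 0.0),
        (0.5, 1.0, 2.0, -0.1931472),      # 2*0.5*ln(0.5) + 0.5
        (0.4, 100.0, 1.4932, -0.0112168),  # term-by-term hand evaluation
    ])
    def test_values(self, phi, m, chi, expected):
        assert delta_g_mix(phi, m, chi) == pytest.approx(expected, abs=1e-5)

    @settings(max_examples=100, derandomize=True)
    @given(m=st.floats(min_value=1.0, max_value=1e6),
           chi=st.floats(min_value=-5.0, max_value=5.0))
    def test_pure_endpoints_are_zero(self, m, chi):
        assert delta_g_mix(0.0, m, chi) == 0.0
        assert delta_g_mix(1.0, m, chi) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(phi=st.floats(min_value=0.0, max_value=1.0),
           chi=st.floats(min_value=-3.0, max_value=3.0))
    def test_symmetric_when_m_is_one(self, phi, chi):
        assert delta_g_mix(phi, 1.0, chi) == pytest.approx(
            delta_g_mix(1.0 - phi, 1.0, chi), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            delta_g_mix(1.2, 100.0, 1.0)


def _fd_spinodal_chi(phi: float, m: float) -> float:
    """Brute-force oracle: the chi at which the finite-difference second
    composition derivative of the free energy vanishes at phi.  Five-point
    central stencil, accurate to O(h^4)."""
    h = 1e-4

    def d2g(chi: float) -> float:
        g = delta_g_mix(
            np.array([phi - 2 * h, phi - h, phi, phi + h, phi + 2 * h]),
            m, chi)
        return (-g[0] + 16 * g[1] - 30 * g[2] + 16 * g[3] - g[4]) / (12 * h**2)

    return brentq(d2g, -50.0, 200.0, xtol=1e-10)


class TestSpinodal:
    @pytest.mark.parametrize("phi, m, expected", [
        (0.5, 1.0, 2.0),                 # symmetric-blend critical value
        (0.5, 1e6, 1.000001),            # polymer term vanishes, long chains
    ])
    def test_closed_form_values(self, phi, m, expected):
        assert spinodal_chi(phi, m) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("m", [1.0, 10.0, 100.0, 1e4])
    def test_matches_finite_difference_oracle(self, m):
        for phi in np.arange(0.05, 0.951, 0.05):
            assert spinodal_chi(float(phi), m) == pytest.approx(
                _fd_spinodal_chi(float(phi), m), abs=1e-6)

    def test_boundary_divergence(self):
        for phi in (0.0, 1.0):
            with pytest.raises(ValueError):
                spinodal_chi(phi, 100.0)


class TestCriticalPoint:
    @pytest.mark.parametrize("m, expected", [
        (1.0, (0.5, 2.0)),
        (100.0, (0.9090909, 0.605)),
        (1e6, (None, 0.5010005)),  # chi_c -> 1/2 in the long-chain limit
    ])
    def test_closed_form(self, m, expected):
        phi_c, chi_c = critical_point(m)
        if expected[0] is not None:
            assert phi_c == pytest.approx(expected[0], abs=1e-6)
        assert chi_c == pytest.approx(expected[1], abs=1e-6)

    def test_is_grid_minimum_of_spinodal(self):
        for m in (1.0, 10.0, 100.0):
            phi_c, chi_c = critical_point(m)
            grid = np.linspace(0.01, 0.99, 981)
            chis = [spinodal_chi(float(p), m) for p in grid]
            i = int(np.argmin(chis))
            assert abs(grid[i] - phi_c) <= 2e-3
            assert chis[i] >= chi_c - 1e-12

    def test_chi_c_decreases_monotonically_to_half(self):
        ms = [1, 4, 16, 64, 256, 1024, 1e5]
        chi_cs = [critical_point(m)[1] for m in ms]
        assert all(a > b for a, b in zip(chi_cs, chi_cs[1:]))
        assert chi_cs[-1] > 0.5


class TestDepressionTransform:
    def test_pure_drug_is_fixed_point(self, mixture):
        ds = MeltingDepressionDataset(points=[(1.0, 415.25), (0.8, 410.0),
                                              (0.6, 405.0)])
        x, y = depression_transform(ds, mixture)[0]
        assert x == pytest.approx(0.0)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_points_fall_on_chi_line(self, mixture):
        # chi small enough that every drug-rich composition still shows
        # depression rather than elevation
        spec = SyntheticSpec(chi_true=0.3, noise_sd_T=0.0)
        ds = simulate_melting_depression(spec, mixture)
        for x, y in depression_transform(ds, mixture):
            assert y == pytest.approx(spec.chi_true * x, abs=1e-9)

    def test_zero_drug_and_elevation_points_rejected(self, mixture):
        ds = MeltingDepressionDataset(points=[(0.0, 400.0), (0.5, 420.0),
                                              (0.8, 410.0), (0.9, 413.0)])
        with pytest.warns(UserWarning):
            out = depression_transform(ds, mixture)
        assert len(out) == 2


class TestChiRegression:
    def test_exact_line(self):
        fit = fit_chi_at_tm([(0.0, 0.0), (0.25, 0.5), (1.0, 2.0)])
        assert fit.chi_at_tm == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_free_round_trip(self, mixture):
        spec = SyntheticSpec(chi_true=0.3, noise_sd_T=0.0)
        ds = simulate_melting_depression(spec, mixture)
        fit = fit_chi_at_tm(depression_transform(ds, mixture))
        assert fit.chi_at_tm == pytest.approx(0.3, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_chi_at_tm([(0.1, 0.0), (0.2, 0.1)])
        with pytest.raises(ValueError):
            fit_chi_at_tm([(0.1, 0.0), (0.1, 0.1), (0.1, 0.2)])

    def test_large_intercept_warns(self):
        with pytest.warns(UserWarning, match="intercept"):
            fit_chi_at_tm([(0.0, 0.5), (0.5, 1.0), (1.0, 1.5)])


class TestHansenChi:
    def test_identical_triples_give_zero(self):
        a = Component(name="a", molar_volume=100.0, hsp=(18.0, 5.0, 7.0))
        b = Component(name="b", hsp=(18.0, 5.0, 7.0))
        assert chi_from_hsp(a, b, 298.15) == 0.0

    def test_hand_checked_value(self):
        a = Component(name="a", molar_volume=100.0, hsp=(20.0, 0.0, 0.0))
        b = Component(name="b", hsp=(18.0, 0.0, 0.0))
        # 100 * 4 / (8.314 * 298.15)
        assert chi_from_hsp(a, b, 298.15) == pytest.approx(0.16137, abs=1e-4)

    def test_felodipine_hpmc_ambient_value(self, mixture):
        chi = chi_from_hsp(mixture.drug, mixture.polymer, 298.0)
        assert chi == pytest.approx(4.11, abs=0.005)

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.floats(0.0, 30.0)] * 6))
    def test_never_negative(self, deltas):
        a = Component(name="a", molar_volume=200.0, hsp=deltas[:3])
        b = Component(name="b", hsp=deltas[3:])
        assert chi_from_hsp(a, b, 350.0) >= 0.0


class TestChiTemperatureModel:
    def test_reference_anchor_fit(self, reference_model):
        # exact linear solve through the two published anchors
        assert abs(reference_model.A) == pytest.approx(8.88, abs=0.005)
        assert reference_model.B == pytest.approx(3872.16, abs=0.1)
        assert reference_model.A < 0  # forced by chi decreasing with 1/T

    def test_two_anchor_fit_reproduces_anchors(self, reference_model):
        for T, chi in [(298.0, 4.11), (415.25, 0.441)]:
            assert chi_at(reference_model, T) == pytest.approx(chi, abs=1e-9)

    def test_flat_line(self):
        model = fit_chi_temperature_model([(300.0, 1.7), (400.0, 1.7)])
        assert model.A == pytest.approx(1.7)
        assert model.B == pytest.approx(0.0, abs=1e-9)

    def test_three_exact_anchors_recovered(self):
        anchors = [(T, 1.0 + 500.0 / T) for T in (280.0, 350.0, 420.0)]
        model = fit_chi_temperature_model(anchors)
        assert model.A == pytest.approx(1.0, abs=1e-9)
        assert model.B == pytest.approx(500.0, abs=1e-6)

    def test_insufficient_anchors_rejected(self):
        with pytest.raises(ValueError):
            fit_chi_temperature_model([(300.0, 1.0)])
        with pytest.raises(ValueError):
            fit_chi_temperature_model([(300.0, 1.0), (300.0, 2.0)])

    @pytest.mark.parametrize("T, expected", [
        (318.15, 3.287),   # stressed storage temperature, 45 degC
        (373.15, 1.493),   # 100 degC
    ])
    def test_extrapolated_values(self, reference_model, T, expected):
        assert chi_at(reference_model, T) == pytest.approx(expected, abs=5e-4)

    def test_monotone_decreasing_when_B_positive(self, reference_model):
        Ts = np.linspace(250.0, 500.0, 40)
        chis = [chi_at(reference_model, float(t)) for t in Ts]
        assert all(a > b for a, b in zip(chis, chis[1:]))


class TestBoundarySolvers:
    def test_no_spinodal_when_miscible(self):
        model = ChiTemperatureModel(A=0.4, B=0.0)  # below chi_c for m=100
        assert spinodal_composition_at_T(model, 100.0, 350.0) == []

    def test_tangency_returns_critical_composition(self):
        phi_c, chi_c = critical_point(100.0)
        model = ChiTemperatureModel(A=chi_c, B=0.0)
        roots = spinodal_composition_at_T(model, 100.0, 350.0)
        assert roots == pytest.approx([phi_c])

    def test_roots_against_dense_grid_oracle(self, reference_model):
        T, m = 318.15, 100.0
        roots = spinodal_composition_at_T(reference_model, m, T)
        assert len(roots) == 2
        assert roots[0] == pytest.approx(0.152, abs=1e-3)
        # oracle: sign changes of chi_s(phi) - chi(T) on a dense grid
        chi_T = chi_at(reference_model, T)
        grid = np.linspace(1e-4, 1 - 1e-4, 200001)
        diff = np.array([spinodal_chi(float(p), m) for p in grid]) - chi_T
        crossings = grid[:-1][np.sign(diff[:-1]) != np.sign(diff[1:])]
        assert len(crossings) == 2
        for root, approx in zip(roots, crossings):
            assert abs(root - approx) < 1e-4

    def test_solubility_is_one_at_melting_point(self, reference_model, mixture):
        assert solubility_boundary_at_T(
            reference_model, mixture, mixture.drug.Tm_pure) == 1.0

    def test_solubility_against_dense_grid_oracle(self, reference_model,
                                                  mixture):
        from asdscreen.constants import R
        T = 318.15
        phi = solubility_boundary_at_T(reference_model, mixture, T)
        assert phi == pytest.approx(7.9e-4, abs=1e-4)
        drug = mixture.drug
        lhs = (1 / T - 1 / drug.Tm_pure) * (drug.dH_fus_molar / -R)
        chi_T = chi_at(reference_model, T)
        grid = np.logspace(-6, -0.0001, 400000)
        rhs = (np.log(grid) + (1 - 1 / mixture.m) * (1 - grid)
               + chi_T * (1 - grid) ** 2)
        sign = np.sign(rhs - lhs)
        crossings = grid[:-1][sign[:-1] != sign[1:]]
        assert len(crossings) >= 1
        assert abs(phi - crossings[0]) < phi * 1e-3

    def test_out_of_range_temperature_rejected(self, reference_model, mixture):
        with pytest.raises(ValueError):
            solubility_boundary_at_T(reference_model, mixture, 500.0)


class TestFoxEquation:
    @pytest.mark.parametrize("X, expected", [
        (1.0, 317.55),
        (0.0, 364.67),
        (0.5, 339.48),  # weight-harmonic mean, hand-checked
    ])
    def test_values(self, X, expected):
        assert tg_mixture(X, 317.55, 364.67) == pytest.approx(expected,
                                                              abs=0.01)

    @settings(max_examples=100, derandomize=True)
    @given(X=st.floats(min_value=0.001, max_value=0.999))
    def test_bounded_by_endpoints(self, X):
        tg = tg_mixture(X, 317.55, 364.67)
        assert 317.55 < tg < 364.67

    def test_monotone_in_composition(self):
        Xs = np.linspace(0, 1, 51)
        tgs = [tg_mixture(float(x), 317.55, 364.67) for x in Xs]
        assert all(a > b for a, b in zip(tgs, tgs[1:]))


class TestClassification:
    def test_low_load_metastable_at_storage(self, reference_model, mixture):
        # 10 % w/w at 45 degC sits between the solubility boundary
        # (~8e-4) and the spinodal root (~0.152): nucleation-limited
        point = state_point(mixture, 318.15, w_drug=0.10)
        label = classify_state(point, reference_model, mixture)
        assert label.stability == "metastable"
        assert label.glass_relation == "below_Tg"

    def test_high_load_unstable_at_storage(self, reference_model, mixture):
        point = state_point(mixture, 318.15, w_drug=0.30)
        label = classify_state(point, reference_model, mixture)
        assert label.stability == "unstable"

    def test_dilute_point_stable(self, reference_model, mixture):
        point = state_point(mixture, 318.15, phi_drug=5e-4)
        assert classify_state(point, reference_model,
                              mixture).stability == "stable"

    def test_monotone_in_composition_at_fixed_T(self, reference_model,
                                                mixture):
        # increasing drug load never jumps from unstable back toward
        # stable without passing through metastable
        order = {"stable": 0, "metastable": 1, "unstable": 2}
        seen = []
        for phi in np.linspace(1e-4, 0.5, 120):
            label = classify_state(
                state_point(mixture, 318.15, phi_drug=float(phi)),
                reference_model, mixture)
            seen.append(order[label.stability])
        assert all(a <= b for a, b in zip(seen, seen[1:]))

    def test_region_codes_match_published_zones(self, reference_model,
                                                mixture):
        # the worked storage scenarios: zone E (metastable, glassy) for
        # the 10 % load at 45 degC, zones H/I (unstable, glassy) for 30 %
        at_45 = classify_state(state_point(mixture, 318.15, w_drug=0.10),
                               reference_model, mixture)
        assert at_45.region_code == "E"
        hot = classify_state(state_point(mixture, 318.15, w_drug=0.30),
                             reference_model, mixture)
        assert hot.region_code == "H"
        cold = classify_state(state_point(mixture, 298.15, w_drug=0.30),
                              reference_model, mixture)
        assert cold.region_code == "I"


class TestPhaseDiagram:
    def test_constant_low_chi_gives_empty_spinodal(self, mixture):
        model = ChiTemperatureModel(A=0.4, B=0.0)
        diagram = build_phase_diagram(model, mixture, n_T=30)
        assert diagram.spinodal_curve == []
        assert len(diagram.solubility_curve) > 0

    def test_reference_diagram_consistent_with_point_queries(
            self, reference_model, mixture):
        diagram = build_phase_diagram(reference_model, mixture, n_T=40)
        spin_T = [t for _, t in diagram.spinodal_curve]
        assert spin_T  # two-phase region exists for this pair
        assert max(spin_T) < 413.0  # closes near the all-miscible temperature
        for phi, T in diagram.spinodal_curve[:10]:
            roots = spinodal_composition_at_T(reference_model, mixture.m, T)
            assert any(abs(phi - r) < 1e-8 for r in roots)
        sol_T = {t for _, t in diagram.solubility_curve}
        assert len(sol_T) == 40  # no gaps for this parameterisation

    def test_grid_refinement_converges(self, reference_model, mixture):
        coarse = build_phase_diagram(reference_model, mixture, n_T=40)
        fine = build_phase_diagram(reference_model, mixture, n_T=79)
        # fine grid contains the coarse temperatures; boundaries agree there
        coarse_sol = dict((round(t, 6), p) for p, t in coarse.solubility_curve)
        fine_sol = dict((round(t, 6), p) for p, t in fine.solubility_curve)
        shared = set(coarse_sol) & set(fine_sol)
        assert len(shared) >= 20
        for t in shared:
            assert coarse_sol[t] == pytest.approx(fine_sol[t], abs=1e-9)

    def test_serialisation_layout(self, reference_model, mixture, tmp_path):
        import json
        diagram = build_phase_diagram(reference_model, mixture, n_T=20)
        path = tmp_path / "diagram.json"
        diagram.to_json(path)
        payload = json.loads(path.read_text())
        assert set(payload["curves"]) == {"solubility", "spinodal", "tg"}
        assert payload["model"]["B"] == pytest.approx(reference_model.B)
        for phi, T in payload["curves"]["solubility"]:
            assert 0.0 < phi <= 1.0
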