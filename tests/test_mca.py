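"""Structural rank, control coefficients and the power-law node fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_structural_rank
from ptsflux.mca import (
    MCAProblem,
    PowerLawFit,
    SingularityError,
    characteristic_curve,
    concentration_control,
    fit_powerlaw_two_points,
    monotonicity_condition,
    node_elasticities,
    reduced_node_problem,
    reduced_steady_state,
    slope_k_from_conditions,
    structural_rank,
)
from ptsflux.synth import reference_flux_table

#: the two (pyruvate -> PEP flux, PEP/pyruvate ratio) calibration points
POINTS = ((4.00, 1.0), (2.93, 0.49))


class TestStructuralRank:
    def test_single_column_pattern_has_rank_one(self):
        assert structural_rank([[1, 0], [1, 0]]) == 1

    def test_diagonal_pattern_has_full_rank(self):
        assert structural_rank([[1, 0], [0, 1]]) == 2

    def test_zero_matrix(self):
        assert structural_rank(np.zeros((3, 4))) == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 2 ** 25 - 1))
    def test_matches_brute_force_on_random_patterns(self, n, m, bits):
        pattern = np.array([(bits >> i) & 1 for i in range(n * m)]).reshape(n, m)
        assert structural_rank(pattern) == brute_force_structural_rank(pattern)


class TestConcentrationControl:
    def test_reduced_node_closed_form(self):
        fit = fit_powerlaw_two_points(*POINTS)
        k = 0.34
        ra = 4.00 / (1 - k)
        eps_c, eps_d = node_elasticities(fit, ra, k)
        dc = concentration_control(reduced_node_problem(fit, ra, k))
        assert dc[0] == pytest.approx((1 - k) / eps_d, rel=1e-12)  # dPEP/dra
        assert dc[1] == pytest.approx((1 - k) / eps_c, rel=1e-12)  # dPyr/dra

    def test_agrees_with_finite_difference_perturbation(self, rng):
        for _ in range(5):
            fit = PowerLawFit(kc=1.0, nc=1.0,
                              kd=10 ** rng.uniform(-0.5, 0.8),
                              nd=10 ** rng.uniform(-0.8, 0.2))
            k = rng.uniform(0.0, 0.8)
            ra = rng.uniform(1.0, 10.0)
            dc = concentration_control(reduced_node_problem(fit, ra, k))
            h = 1e-6 * ra
            hi = reduced_steady_state(ra + h, k, fit)
            lo = reduced_steady_state(ra - h, k, fit)
            fd = [(hi[0] - lo[0]) / (2 * h), (hi[1] - lo[1]) / (2 * h)]
            assert dc[0] == pytest.approx(fd[0], rel=1e-5)
            assert dc[1] == pytest.approx(fd[1], rel=1e-5)

    def test_zero_row_elasticity_is_a_structural_singularity(self):
        problem = MCAProblem(np.array([[0.0, 0.0], [1.0, 0.0]]),
                             np.eye(2), np.eye(2), [1.0, 0.0])
        with pytest.raises(SingularityError, match="structural rank"):
            concentration_control(problem)

    def test_one_sided_dependency_pattern_not_invertible(self):
        # both unknown rates depending on the same metabolite only
        problem = MCAProblem(np.array([[1.0, 0.0], [1.0, 0.0]]),
                             np.eye(2), np.eye(2), [1.0, 0.0])
        with pytest.raises(SingularityError):
            concentration_control(problem)


class TestTwoPointFit:
    def test_exponent_ratio_rounds_to_030(self):
        fit = fit_powerlaw_two_points(*POINTS)
        assert round(fit.nd / fit.nc, 2) == 0.30
        # the companion constant from the closed form (~2.6) is logged,
        # not asserted against any external value
        assert 2.0 < fit.kd < 3.0

    def test_ratio_law_passes_through_both_points(self):
        fit = fit_powerlaw_two_points(*POINTS)
        for rc, pp in POINTS:
            assert fit.pep_pyruvate_ratio(rc) == pytest.approx(pp, rel=1e-12)

    def test_round_trip_from_known_constants(self):
        truth = PowerLawFit(kc=1.0, nc=1.0, kd=2.2, nd=0.41)
        pts = [(rc, float(truth.pep_pyruvate_ratio(rc))) for rc in (1.7, 5.3)]
        fit = fit_powerlaw_two_points(*pts)
        assert fit.kd == pytest.approx(truth.kd, rel=1e-10)
        assert fit.nd == pytest.approx(truth.nd, rel=1e-10)

    def test_alpha_times_kd_equals_kc(self):
        fit = fit_powerlaw_two_points(*POINTS, kc=3.0, nc=1.0)
        assert fit.alpha * fit.kd == pytest.approx(fit.kc, abs=1e-12)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_powerlaw_two_points((2.0, 1.0), (2.0, 0.5))
        with pytest.raises(ValueError):
            fit_powerlaw_two_points((2.0, -1.0), (3.0, 0.5))


class TestReducedSteadyState:
    def test_reproduces_the_reference_ratio(self):
        fit = fit_powerlaw_two_points(*POINTS)
        k = 0.344
        pep, pyr, pp = reduced_steady_state(4.00 / (1 - k), k, fit)
        assert pp == pytest.approx(1.0, rel=1e-10)

    def test_symmetric_kinetics_pin_the_ratio_at_one(self):
        fit = PowerLawFit(kc=1.0, nc=1.0, kd=1.0, nd=1.0)
        for ra in (0.5, 2.0, 9.0):
            pep, pyr, pp = reduced_steady_state(ra, 0.3, fit)
            assert pep == pytest.approx(pyr) and pp == pytest.approx(1.0)

    def test_agrees_with_numeric_root_find(self, rng):
        from scipy.optimize import brentq
        for _ in range(5):
            fit = PowerLawFit(kc=1.0, nc=1.0, kd=rng.uniform(0.5, 4),
                              nd=rng.uniform(0.2, 1.5))
            k, ra = rng.uniform(0, 0.8), rng.uniform(0.5, 8)
            flux = (1 - k) * ra
            pyr = brentq(lambda c: fit.kc * c ** fit.nc - flux, 1e-12, 1e12,
                         xtol=1e-15, rtol=8.9e-16)
            pep = brentq(lambda c: fit.kd * c ** fit.nd - flux, 1e-12, 1e12,
                         xtol=1e-15, rtol=8.9e-16)
            got = reduced_steady_state(ra, k, fit)
            assert got[0] == pytest.approx(pep, rel=1e-10)
            assert got[1] == pytest.approx(pyr, rel=1e-10)

    def test_no_steady_state_when_drain_takes_everything(self):
        fit = fit_powerlaw_two_points(*POINTS)
        with pytest.raises(ValueError):
            reduced_steady_state(4.0, 1.0, fit)


class TestMonotonicity:
    def test_fitted_exponents_satisfy_the_condition(self):
        fit = fit_powerlaw_two_points(*POINTS)
        assert monotonicity_condition(fit.nc, fit.nd) is True

    def test_boundary_is_excluded(self):
        assert monotonicity_condition(1.0, 1.0) is False

    @pytest.mark.parametrize("nc,nd", [(1.0, 0.30), (1.0, 2.0)])
    def test_ratio_increases_on_a_grid_iff_condition_holds(self, nc, nd):
        fit = PowerLawFit(kc=1.0, nc=nc, kd=1.3, nd=nd)
        ra = np.linspace(0.5, 10, 40)
        pp = np.array([reduced_steady_state(r, 0.3, fit)[2] for r in ra])
        increasing = bool(np.all(np.diff(pp) > 0))
        assert increasing == monotonicity_condition(nc, nd)


class TestCharacteristicCurve:
    def setup_method(self):
        self.fit = fit_powerlaw_two_points(*POINTS)
        self.k = slope_k_from_conditions(reference_flux_table())

    def test_band_collapses_at_a_single_slope(self):
        curve = characteristic_curve(self.fit, self.k, (self.k, self.k),
                                     np.linspace(1, 10, 9))
        assert np.allclose(curve["pp_lo"], curve["pp"])
        assert np.allclose(curve["pp_hi"], curve["pp"])

    def test_curve_passes_through_the_calibration_points(self):
        ra = [rc / (1 - self.k) for rc, _ in POINTS]
        curve = characteristic_curve(self.fit, self.k, (0.2, 0.5), ra)
        for (rc, pp), got in zip(POINTS, curve["pp"]):
            assert got == pytest.approx(pp, rel=1e-10)

    def test_band_edges_are_valid_monotone_curves(self):
        curve = characteristic_curve(self.fit, self.k, (0.1, 0.6),
                                     np.linspace(0.5, 12, 30))
        assert np.all(np.diff(curve["pp_lo"]) > 0)
        assert np.all(np.diff(curve["pp_hi"]) > 0)
        assert (curve["pp_lo"] <= curve["pp"] + 1e-12).all()
        assert (curve["pp"] <= curve["pp_hi"] + 1e-12).all()


class TestSlopeK:
    def test_node_closure_slope_from_reference_fluxes(self):
        # rb = ra - rc: (6.32-4.00) -> (4.69-2.93) over ra 6.32 -> 4.69
        k = slope_k_from_conditions(reference_flux_table())
        assert k == pytest.approx((2.32 - 1.76) / (6.32 - 4.69), rel=1e-12)
        assert k == pytest.approx(0.344, abs=5e-4)

    def test_acetyl_coa_mode_uses_the_printed_drain(self):
        k = slope_k_from_conditions(reference_flux_table(), mode="acetyl-coa")
        assert k == pytest.approx((1.83 - 1.47) / (6.32 - 4.69), rel=1e-12)

    def test_identical_drain_gives_zero_slope(self):
        tab = pd.DataFrame({
            "condition": ["a", "a", "b", "b"],
            "reaction": ["oaa_to_pyr", "pyr_to_pep"] * 2,
            "nominal": [6.0, 4.0, 4.0, 2.0],
        })
        assert slope_k_from_conditions(tab) == 0.0

    def test_equal_input_fluxes_rejected(self):
        tab = pd.DataFrame({
            "condition": ["a", "a", "b", "b"],
            "reaction": ["oaa_to_pyr", "pyr_to_pep"] * 2,
            "nominal": [6.0, 4.0, 6.0, 3.0],
        })
        with pytest.raises(ValueError, match="equal"):
            slope_k_from_conditions(tab)

    def test_fva_extremes_span_a_band_containing_the_nominal_slope(self):
        tab = reference_flux_table()
        k_nom = slope_k_from_conditions(tab)
        slopes = []
        for va in ("min", "max"):
            for vc in ("min", "max"):
                t = tab.copy()
                t["nominal"] = np.where(t["reaction"] == "oaa_to_pyr",
                                        t[va], np.where(
                                            t["reaction"] == "pyr_to_pep",
                                            t[vc], t["nominal"]))
                slopes.append(slope_k_from_conditions(t))
        assert min(slopes) <= k_nom <= max(slopes)
        assert max(slopes) > min(slopes)
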