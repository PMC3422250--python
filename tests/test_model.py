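"""Core dynamics: forcing term, Euler integrator, analytic oracle, DTI."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from tasseltime import (
    DGNParameters,
    GenotypeSpec,
    HorizonExhaustedError,
    SimulationSettings,
    closed_form,
    closed_form_dti,
    predict_dti,
    regulatory_input,
    simulate,
)
from tasseltime.model import _euler_levels, derivative


positive = st.floats(1e-4, 1e2, allow_nan=False, allow_infinity=False)


def params_strategy():
    return st.builds(
        DGNParameters,
        alpha1=st.floats(1e-4, 1.0),
        alpha2=st.floats(1e-3, 100.0),
        alpha3=st.floats(1e-3, 100.0),
        beta=st.floats(1e-3, 10.0),
        omega=st.floats(1e-3, 1.0),
    )


class TestRegulatoryInput:
    @pytest.mark.parametrize(
        "name, expected_c",
        [
            ("Gaspe Flint", 0.12303190),   # 0.002*(1 + 6.489431 + 53.204799 + 0.821720)
            ("B73", 0.016622302),
            ("dlf1 mutant", 0.00364344),
            ("id1 mutant", 0.00164344),    # alpha1*beta only
            ("id1 dlf1", 0.00164344),
            ("ZMM4 B73", 0.018265742),     # beta doubled by the transgene
        ],
    )
    def test_forcing_constants(self, by_name, ref_params, name, expected_c):
        assert regulatory_input(by_name[name], ref_params) == pytest.approx(
            expected_c, rel=1e-9
        )

    def test_id1_knockout_silences_dlf1(self, by_name, ref_params):
        """ID1=0 annihilates both the ID1 and ID1*DLF1 terms, so the id1
        single mutant and the double mutant share one forcing constant."""
        assert regulatory_input(by_name["id1 mutant"], ref_params) == regulatory_input(
            by_name["id1 dlf1"], ref_params
        )

    @given(params=params_strategy())
    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_positive_for_positive_params(self, params):
        for bits in range(16):
            g = GenotypeSpec("g", bits & 1, (bits >> 1) & 1, (bits >> 2) & 1, (bits >> 3) & 1)
            assert regulatory_input(g, params) > 0

    def test_transgene_doubles_basal_term_only(self, by_name, ref_params):
        base = regulatory_input(by_name["B73"], ref_params)
        tg = regulatory_input(by_name["ZMM4 B73"], ref_params)
        assert tg - base == pytest.approx(ref_params.alpha1 * ref_params.beta)


class TestDerivative:
    def test_feedback_vanishes_at_zero(self, ref_params):
        assert derivative(0.0, 0.5, ref_params) == 0.5

    def test_value_at_threshold(self, ref_params):
        # c + omega * m with B73's forcing at m = 1
        assert derivative(1.0, 0.0166223, ref_params) == pytest.approx(0.1034043)

    def test_no_feedback_when_omega_zero(self):
        p = DGNParameters(0.01, 1.0, 1.0, 1.0, 1e-300)  # omega ~ 0 but positive
        assert derivative(5.0, 0.2, p) == pytest.approx(0.2)


class TestClosedForm:
    def test_initial_condition(self):
        assert closed_form(0.3, 0.1, 0.0) == 0.0
        assert closed_form(0.3, 0.0, 0.0) == 0.0

    def test_omega_zero_limit_is_linear(self):
        t = np.linspace(0, 50, 7)
        np.testing.assert_allclose(
            closed_form(0.02, 1e-12, t), 0.02 * t, rtol=1e-9
        )

    def test_inverts_to_crossing_time(self):
        c, omega = 0.0166223, 0.086782
        t_star = closed_form_dti(c, omega)
        assert closed_form(c, omega, t_star) == pytest.approx(1.0, rel=1e-12)
        assert t_star == pytest.approx(21.063, abs=5e-3)

    def test_unreachable_threshold_is_infinite(self):
        assert closed_form_dti(0.0, 0.1) == np.inf


class TestEulerIntegrator:
    def test_matches_literal_recurrence(self):
        """The vectorized geometric form is the Euler recurrence itself."""
        c, omega, dt, m0 = 0.0166223, 0.086782, 0.05, 0.0
        m = m0
        literal = [m]
        for _ in range(200):
            m = m + dt * (c + omega * m)
            literal.append(m)
        np.testing.assert_allclose(
            _euler_levels(c, omega, dt, m0, 200), literal, rtol=1e-12
        )

    def test_zero_forcing_stays_at_zero(self, settings):
        g = GenotypeSpec("null", 0, 0, 0, 0)
        p = DGNParameters(1e-12, 1.0, 1.0, 1e-12, 1e-12)  # c ~ 0
        traj = simulate(g, p, settings)
        assert traj.mzmm4.max() < 1e-6
        assert traj.dti is None

    def test_agrees_with_closed_form_within_half_percent(self, panel, ref_params, settings):
        """Euler at dt=0.01 tracks the analytic solution to <0.5% relative
        error over [0, DTI] for every reference genotype."""
        for g in panel:
            traj = simulate(g, ref_params, settings)
            c = regulatory_input(g, ref_params)
            upto = traj.times <= traj.dti
            exact = closed_form(c, ref_params.omega, traj.times[upto])
            rel = np.abs(traj.mzmm4[upto][1:] - exact[1:]) / exact[1:]
            assert rel.max() < 0.005, g.name

    def test_first_order_convergence(self, by_name, ref_params):
        """Halving dt halves the DTI error against the analytic crossing."""
        g = by_name["B73"]
        c = regulatory_input(g, ref_params)
        t_star = closed_form_dti(c, ref_params.omega)
        errors = []
        for dt in (0.02, 0.01, 0.005):
            dti = predict_dti(g, ref_params, SimulationSettings(dt=dt))
            errors.append(abs(dti - t_star))
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.1)
        assert errors[1] / errors[2] == pytest.approx(2.0, rel=0.1)


class TestTrajectory:
    def test_invariants(self, panel, ref_params, settings):
        for g in panel:
            traj = simulate(g, ref_params, settings)
            assert traj.times[0] == 0.0
            assert np.all(np.diff(traj.times) > 0)
            assert np.all(np.diff(traj.mzmm4) >= 0)
            assert np.all(np.diff(traj.fts) >= 0)  # step function, never unflips
            # fts is 0 strictly before dti and 1 at/after
            assert np.all(traj.fts[traj.times < traj.dti - settings.dt] == 0)
            assert np.all(traj.fts[traj.times >= traj.dti] == 1)

    def test_dti_invariant_to_horizon(self, by_name, ref_params):
        g = by_name["id1 mutant"]
        d1 = predict_dti(g, ref_params, SimulationSettings(t_max=50.0))
        d2 = predict_dti(g, ref_params, SimulationSettings(t_max=200.0))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_horizon_exhaustion_raises(self, by_name, ref_params):
        with pytest.raises(HorizonExhaustedError, match="id1 mutant"):
            predict_dti(by_name["id1 mutant"], ref_params, SimulationSettings(t_max=10.0))


class TestPredictDTI:
    @pytest.mark.parametrize(
        "name, expected_dti",
        [
            # analytic crossing times t* = ln(1 + omega/c)/omega
            ("Gaspe Flint", 6.1508),
            ("B73", 21.0631),
            ("dlf1 mutant", 37.0076),
            ("id1 mutant", 45.9239),
            ("ZMM4 B73", 20.1584),
        ],
    )
    def test_reference_crossing_times(self, by_name, ref_params, settings, name, expected_dti):
        dti = predict_dti(by_name[name], ref_params, settings)
        assert dti == pytest.approx(expected_dti, rel=5e-3)  # within Euler error

    @given(params=params_strategy())
    @hyp_settings(max_examples=30, deadline=None, derandomize=True)
    def test_gain_of_function_never_delays(self, params):
        """Adding any functional allele (or the transgene) can only speed
        the transition: DTI is decreasing in each forcing component."""
        s = SimulationSettings(t_max=1e4)

        def dti(vgt1, id1, dlf1, tg):
            c = regulatory_input(GenotypeSpec("g", vgt1, id1, dlf1, tg), params)
            return closed_form_dti(c, params.omega)

        assert dti(1, 0, 0, 0) < dti(0, 0, 0, 0)
        assert dti(0, 1, 0, 0) < dti(0, 0, 0, 0)
        assert dti(0, 1, 1, 0) < dti(0, 1, 0, 0)
        assert dti(0, 0, 0, 1) < dti(0, 0, 0, 0)


class TestValidation:
    def test_rejects_non_binary_alleles(self):
        with pytest.raises(ValueError, match="must be 0 or 1"):
            GenotypeSpec("bad", 2, 0, 0, 0)

    def test_rejects_non_positive_parameters(self):
        with pytest.raises(ValueError, match="strictly positive"):
            DGNParameters(0.0, 1.0, 1.0, 1.0, 0.1)
        with pytest.raises(ValueError, match="omega"):
            DGNParameters(0.1, 1.0, 1.0, 1.0, -0.1)

    def test_rejects_threshold_below_initial_value(self):
        with pytest.raises(ValueError, match="threshold"):
            SimulationSettings(m0=2.0, threshold=1.0)
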