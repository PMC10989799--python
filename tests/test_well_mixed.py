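import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdolsim import ModelParams, simulate_batch, toxicity_factor
from mdolsim.well_mixed import (
    NSTATE, SimulationError, derivatives, initial_state, jacobian,
    product_leakiness, steady_state_fraction, Trajectory, SWEEP_PROTOCOL,
)


class TestToxicityFactor:
    def test_no_toxicity_is_identity(self):
        p = ModelParams(theta=0.0)
        assert toxicity_factor(p, 123.4) == 1.0

    def test_reciprocal_value(self):
        p = ModelParams(theta=0.5, toxicity_form="reciprocal")
        assert toxicity_factor(p, 2.0) == pytest.approx(0.5)

    def test_zero_substrate_is_harmless(self):
        for form in ("reciprocal", "exponential", "linear"):
            p = ModelParams(theta=0.9, toxicity_form=form)
            assert toxicity_factor(p, 0.0) == pytest.approx(1.0)

    def test_form_none_ignores_theta(self):
        p = ModelParams(theta=5.0, toxicity_form="none")
        assert toxicity_factor(p, 10.0) == 1.0

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            toxicity_factor(ModelParams(), -0.1)

    @pytest.mark.parametrize("form", ["reciprocal", "exponential", "linear"])
    @given(s=st.floats(0, 1e3), ds=st.floats(0, 1e3),
           theta=st.floats(0, 10), dtheta=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_in_substrate_and_theta(self, form, s, ds,
                                                   theta, dtheta):
        p = ModelParams(theta=theta, toxicity_form=form)
        assert toxicity_factor(p, s + ds) <= toxicity_factor(p, s) + 1e-12
        p2 = ModelParams(theta=theta + dtheta, toxicity_form=form)
        assert toxicity_factor(p2, s) <= toxicity_factor(p, s) + 1e-12


class TestDerivatives:
    def test_transport_only_at_start(self):
        p = ModelParams(toxicity_form="none", theta=0.0, s0=50.0)
        y = np.zeros(NSTATE)
        y[6] = p.s0
        y[9] = y[10] = 1e-3
        f = derivatives(y, p)
        assert f[0] == pytest.approx(p.gamma_s * p.s0)   # s1_in filling
        assert f[1] == pytest.approx(p.gamma_s * p.s0)   # s2_in filling
        assert f[6] == pytest.approx(-(y[9] + y[10]) * p.gamma_s * p.s0)
        assert f[9] == 0.0 and f[10] == 0.0              # no product yet

    def test_equilibrated_substrate_exchange_vanishes(self):
        p = ModelParams(gamma_i=0.0)  # isolate reaction flux in i1
        y = np.zeros(NSTATE)
        y[0] = y[6] = 3.0
        f = derivatives(y, p)
        # only the conversion term remains in ds1_in
        assert f[0] == pytest.approx(-p.alpha1 * 3.0 / 4.0)

    def test_reaction_rate_arithmetic(self):
        p = ModelParams(alpha1=10_000.0, gamma_i=0.0)
        y = np.zeros(NSTATE)
        y[0] = 1.0
        f = derivatives(y, p)
        assert f[2] == pytest.approx(5_000.0)  # alpha1 * 1 / (1 + 1)

    def test_nonfinite_state_raises(self):
        y = np.zeros(NSTATE)
        y[0] = np.nan
        with pytest.raises(SimulationError):
            derivatives(y, ModelParams())

    @pytest.mark.parametrize("form", ["none", "reciprocal", "exponential",
                                      "linear"])
    def test_jacobian_matches_finite_differences(self, form):
        rng = np.random.default_rng(7)
        p = ModelParams(theta=0.02, toxicity_form=form, death_rate=1e-4)
        y = rng.uniform(0.1, 2.0, NSTATE)
        J = jacobian(y, p)
        eps = 1e-7
        for j in range(NSTATE):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps
            ym[j] -= eps
            col = (derivatives(yp, p) - derivatives(ym, p)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], col, rtol=2e-5, atol=1e-6)


class TestSimulateBatch:
    def test_no_substrate_no_growth(self):
        p = ModelParams(toxicity_form="none", theta=0.0, s0=0.0)
        traj = simulate_batch(p)
        ss = traj.steady_state
        assert ss.converged
        assert ss.df == pytest.approx(0.5)
        y0 = initial_state(p)
        assert traj["x1"][-1] == pytest.approx(y0[9])
        assert traj["x2"][-1] == pytest.approx(y0[10])

    def test_missing_detoxifier_breaks_pathway(self):
        p = ModelParams(toxicity_form="none", theta=0.0, s0=100.0)
        y0 = initial_state(p, detoxifier_share=0.0)
        traj = simulate_batch(p, init=y0, tau_max=2e4)
        assert traj["i_out"].max() == pytest.approx(0.0, abs=1e-10)
        assert traj["p_out"].max() == pytest.approx(0.0, abs=1e-10)
        assert traj["x2"][-1] == pytest.approx(y0[10], rel=1e-6)
        assert product_leakiness(traj) == 0.0

    def test_states_stay_nonnegative(self, rep_notox):
        traj = simulate_batch(rep_notox.replace(s0=100.0))
        assert traj.states[:11].min() >= -1e-8

    def test_aux_integrals_monotone(self, rep_notox):
        traj = simulate_batch(rep_notox.replace(s0=100.0))
        assert np.all(np.diff(traj["aux_p_synth"]) >= -1e-9)

    def test_no_leak_without_product_transport(self, rep_notox):
        traj = simulate_batch(rep_notox.replace(gamma_p=0.0, s0=100.0),
                              tau_max=2e4)
        assert product_leakiness(traj) == pytest.approx(0.0, abs=1e-12)

    def test_fraction_monotone_in_substrate(self, rep_notox):
        dfs = [simulate_batch(rep_notox.replace(s0=s0),
                              protocol=SWEEP_PROTOCOL).steady_state.df
               for s0 in (10.0, 100.0, 1000.0)]
        assert dfs[0] <= dfs[1] <= dfs[2]
        assert all(df < 0.5 for df in dfs)

    def test_leakiness_increases_with_substrate(self, rep_notox):
        # full-episode leakiness: use the default protocol, which keeps
        # integrating after the biomass reaches carrying capacity
        lo = simulate_batch(rep_notox.replace(s0=10.0))
        hi = simulate_batch(rep_notox.replace(s0=1000.0))
        assert (product_leakiness(hi) > product_leakiness(lo))

    def test_fraction_monotone_in_toxicity(self):
        base = ModelParams(toxicity_form="reciprocal", s0=300.0)
        dfs = [simulate_batch(base.replace(theta=th),
                              protocol=SWEEP_PROTOCOL).steady_state.df
               for th in (0.0, 0.003, 0.03)]
        assert dfs[0] <= dfs[1] <= dfs[2]

    def test_invalid_inputs(self, rep_notox):
        with pytest.raises(ValueError):
            simulate_batch(rep_notox, tau_max=-1.0)
        bad = initial_state(rep_notox)
        bad[6] = -1.0
        with pytest.raises(ValueError):
            simulate_batch(rep_notox, init=bad)


class TestSteadyStateAccessors:
    def _traj(self, x1, x2):
        states = np.zeros((NSTATE, 2))
        states[9] = x1
        states[10] = x2
        return Trajectory(tau=np.array([0.0, 1.0]), states=states,
                          params=ModelParams())

    def test_fraction_arithmetic(self):
        assert steady_state_fraction(self._traj(0.003, 0.007)) == \
            pytest.approx(0.3)
        assert steady_state_fraction(self._traj(1.0, 1.0)) == 0.5

    def test_zero_biomass_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            steady_state_fraction(self._traj(0.0, 0.0))

    def test_leakiness_zero_when_no_synthesis(self):
        traj = self._traj(1.0, 1.0)
        assert product_leakiness(traj) == 0.0
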