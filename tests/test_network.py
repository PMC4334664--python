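"""Structure and dynamics of the two-source CMC network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cmcsd
from cmcsd.network import (
    INTRINSIC_CONNECTIONS,
    INTRINSIC_GAIN_UNIT,
    N_POP,
    OBS_WEIGHT_PRIOR,
    TIME_CONSTANT_PRIOR_MS,
    Population,
    build_network,
    jacobian,
    reversed_structure,
    sigmoid_rate,
    state_derivatives,
)


class TestPriorMeans:
    def test_theta_zero_reproduces_printed_table_values(self, prior_params):
        """theta = 0 must give the tabulated priors bit-exactly."""
        expected_g = (4.0, 4.0, 4.0, 4.0, 4.0, 2.0, 4.0, 4.0, 2.0, 1.0)
        for s in range(2):
            assert tuple(prior_params.intrinsic_gains(s)) == expected_g
            assert tuple(
                prior_params.time_constants_s(s) * 1e3
            ) == TIME_CONSTANT_PRIOR_MS
        assert tuple(prior_params.obs_weights()) == OBS_WEIGHT_PRIOR
        assert prior_params.value("slope") == 2.0 / 3.0
        assert prior_params.value("delay_ms") == 16.0

    def test_log_scaling_positivity(self, prior_params):
        params = prior_params.with_updates({"G1_s0": -3.0, "T_SS_s1": 2.0})
        assert params.value("G1_s0") == pytest.approx(4.0 * np.exp(-3.0))
        assert params.value("T_SS_s1") == pytest.approx(2.0 * np.exp(2.0))
        assert all(
            params.value(n) > 0 for n in params.prior.names if "j_II" not in n
        )


class TestConnectivity:
    def test_intrinsic_weights_and_signs(self, prior_params):
        st_ = build_network(prior_params, "veridical")
        for name, src, tgt, sign, mean in INTRINSIC_CONNECTIONS:
            for s in range(2):
                w = st_.weights_intrinsic[N_POP * s + tgt, N_POP * s + src]
                assert w == sign * INTRINSIC_GAIN_UNIT * mean

    def test_sign_antisymmetry_of_reciprocal_pairs(self, prior_params):
        """Every reciprocally connected pair has one + and one - direction;
        all self-connections are inhibitory."""
        st_ = build_network(prior_params, "veridical")
        A = st_.signed_adjacency()
        n = A.shape[0]
        for i in range(n):
            assert A[i, i] <= 0
            for j in range(i + 1, n):
                if A[i, j] != 0 and A[j, i] != 0:
                    assert A[i, j] * A[j, i] == -1
        # extrinsic alone: forward excitatory, backward inhibitory
        E = np.sign(st_.weights_extrinsic)
        assert E[N_POP + Population.SS, Population.SPC] == 1
        assert E[Population.SPC, N_POP + Population.DPC] == -1
        assert E[Population.II, N_POP + Population.DPC] == -1

    def test_reversed_swaps_forward_backward_roles(self, prior_params):
        v = build_network(prior_params, "veridical")
        r = build_network(prior_params, "reversed")
        assert np.array_equal(v.weights_intrinsic, r.weights_intrinsic)
        # in the reversed model, source 1 sends the SPC-origin projection
        assert r.weights_extrinsic[Population.SS, N_POP + Population.SPC] > 0
        assert r.weights_extrinsic[N_POP + Population.SPC, Population.DPC] < 0

    def test_reversal_is_an_involution(self, prior):
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.2, prior.n_params)
        params = cmcsd.CMCParameters(theta, prior)
        g = build_network(params, "veridical")
        gg = reversed_structure(reversed_structure(g))
        assert gg.direction == g.direction
        assert np.array_equal(gg.weights_extrinsic, g.weights_extrinsic)
        assert np.array_equal(
            reversed_structure(g).weights_extrinsic,
            build_network(params, "reversed").weights_extrinsic,
        )

    def test_zero_extrinsic_coupling_decouples_sources(self, prior_params):
        params = prior_params.with_updates({"a_forward": -80.0, "a_backward": -80.0})
        st_ = build_network(params, "veridical")
        off_diag = st_.weights_extrinsic.copy()
        assert np.abs(off_diag).max() < 1e-25
        # intrinsic blocks do not couple across sources
        W = st_.weights_intrinsic
        assert np.all(W[:N_POP, N_POP:] == 0) and np.all(W[N_POP:, :N_POP] == 0)

    def test_unknown_direction_rejected(self, prior_params):
        with pytest.raises(ValueError, match="unknown direction"):
            build_network(prior_params, "sideways")

    def test_optional_forward_termination_on_deep_cells(self, prior_params):
        default = build_network(prior_params, "veridical")
        wide = build_network(prior_params, "veridical", forward_to_dpc=True)
        i, j = N_POP + Population.DPC, Population.SPC
        assert default.weights_extrinsic[i, j] == 0
        assert wide.weights_extrinsic[i, j] > 0
        # the granular termination itself is unchanged
        k = N_POP + Population.SS
        assert wide.weights_extrinsic[k, j] == default.weights_extrinsic[k, j]


class TestSigmoid:
    def test_centering_and_slope(self):
        assert sigmoid_rate(0.0, 2.0 / 3.0) == 0.0
        # derivative at 0 equals slope / 4 (finite-difference check)
        for s in (2.0 / 3.0, 1.0, 3.0):
            h = 1e-6
            fd = (sigmoid_rate(h, s) - sigmoid_rate(-h, s)) / (2 * h)
            assert fd == pytest.approx(s / 4.0, rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(v=st.floats(-50, 50), s=st.floats(0.1, 5.0))
    def test_bounded_monotone_antisymmetric(self, v, s):
        r = sigmoid_rate(v, s)
        assert -0.5 <= r <= 0.5
        assert sigmoid_rate(-v, s) == pytest.approx(-r, abs=1e-12)
        assert sigmoid_rate(v + 0.1, s) >= r


class TestDynamics:
    def test_origin_is_fixed_point(self, prior_params):
        st_ = build_network(prior_params, "veridical")
        dx = state_derivatives(np.zeros(16), st_, np.zeros(2))
        assert np.all(dx == 0.0)

    def test_exogenous_input_enters_ss_only(self, prior_params):
        st_ = build_network(prior_params, "veridical")
        dx = state_derivatives(np.zeros(16), st_, np.array([1.0, 2.0]))
        wdot = dx[8:]
        expected = np.zeros(8)
        expected[Population.SS] = st_.kappa[Population.SS] * 1.0
        expected[N_POP + Population.SS] = st_.kappa[N_POP + Population.SS] * 2.0
        assert np.allclose(wdot, expected)

    @pytest.mark.parametrize(
        "pop, peak_ms", [(Population.SS, 2.0), (Population.DPC, 28.0)]
    )
    def test_alpha_kernel_peaks_at_time_constant(self, prior, pop, peak_ms):
        """An isolated population's impulse response is the alpha kernel
        kappa^2 t exp(-kappa t), peaking at t = T."""
        # silence all coupling so the population is an isolated second-order cell
        updates = {f"{name}_s{s}": -80.0 for name, *_ in INTRINSIC_CONNECTIONS
                   for s in range(2)}
        updates |= {"a_forward": -80.0, "a_backward": -80.0}
        params = cmcsd.CMCParameters.from_prior(prior).with_updates(updates)
        st_ = build_network(params, "veridical")
        idx = int(pop)
        kappa = st_.kappa[idx]
        dt = 1e-5
        n = int(5 * peak_ms * 1e-3 / dt)
        x = np.zeros(16)
        x[8 + idx] = kappa  # state just after a unit impulse of drive
        vs = np.empty(n)
        for t in range(n):
            dx = state_derivatives(x, st_)
            x = x + dt * dx
            vs[t] = x[idx]
        t_peak = (np.argmax(vs) + 1) * dt
        assert t_peak == pytest.approx(peak_ms * 1e-3, rel=0.01)
        # closed form: v(t) = kappa t exp(-kappa t), so v(T) = exp(-1)
        analytic = kappa * peak_ms * 1e-3 * np.exp(-1.0)
        assert vs.max() == pytest.approx(analytic, rel=0.01)

    def test_numerical_jacobian_matches_analytic(self, prior):
        rng = np.random.default_rng(5)
        params = cmcsd.CMCParameters(rng.normal(0, 0.15, prior.n_params), prior)
        st_ = build_network(params, "veridical")
        J_analytic = jacobian(st_)
        h = 1e-6
        J_num = np.empty((16, 16))
        for i in range(16):
            e = np.zeros(16)
            e[i] = h
            J_num[:, i] = (
                state_derivatives(e, st_) - state_derivatives(-e, st_)
            ) / (2 * h)
        scale = np.abs(J_analytic).max()
        assert np.abs(J_num - J_analytic).max() / scale < 1e-6

    def test_degenerate_time_constant_rejected(self, prior_params):
        # exp(-800) underflows to a zero time constant -> infinite rate
        bad = prior_params.with_updates({"T_SS_s0": -800.0})
        with pytest.raises(ValueError):
            build_network(bad, "veridical")
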