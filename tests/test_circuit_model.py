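import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epvsom import (
    CircuitParams,
    cellular_gain,
    inverse_transfer,
    signed_weight_matrix,
    simulate,
    transfer,
)


@pytest.fixture
def default_params():
    return CircuitParams.from_weights()


class TestTransfer:
    @pytest.mark.parametrize(
        "q, expected", [(2.0, 1.0), (-3.0, 0.0), (4.0, 4.0), (0.0, 0.0)]
    )
    def test_power_law_values(self, default_params, q, expected):
        assert transfer(q, default_params)[0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(r=st.floats(0, 100))
    def test_inverse_roundtrip(self, r):
        p = CircuitParams.from_weights()
        assert transfer(inverse_transfer(r, p), p)[0] == pytest.approx(r, abs=1e-9)

    def test_inverse_rejects_negative_rates(self, default_params):
        with pytest.raises(ValueError):
            inverse_transfer(-1.0, default_params)

    def test_monotone_and_rectified(self, default_params):
        q = np.linspace(-5, 5, 201)
        f = np.array([transfer(x, default_params)[0] for x in q])
        assert np.all(np.diff(f) >= 0)
        assert np.all(f[q <= 0] == 0)


class TestCellularGain:
    def test_matches_finite_difference(self, default_params):
        h = 1e-6
        for q in (0.5, 1.0, 4.0):
            fd = (transfer(q + h, default_params) - transfer(q - h, default_params)) / (
                2 * h
            )
            assert cellular_gain(q, default_params)[0] == pytest.approx(
                fd[0], rel=1e-6
            )

    def test_gain_is_sqrt_rate_for_default_transfer(self, default_params):
        # alpha=1/4, beta=2: b = alpha*beta*(r/alpha)^{1/2} = sqrt(r)
        for r in (0.5, 1.0, 4.0, 9.0):
            q = inverse_transfer(r, default_params)
            assert cellular_gain(q, default_params)[0] == pytest.approx(np.sqrt(r))

    def test_linear_transfer_has_constant_gain(self):
        p = CircuitParams.from_weights(beta=1.0)
        for q in (0.1, 1.0, 10.0):
            assert cellular_gain(q, p)[0] == pytest.approx(p.alpha[0])

    def test_rejects_rectified_branch(self, default_params):
        with pytest.raises(ValueError, match="rectification"):
            cellular_gain(np.array([1.0, -0.5, 1.0]), default_params)


class TestSignedWeights:
    def test_sign_pattern_from_identities(self):
        p = CircuitParams(weights=np.full((3, 3), 0.5))
        W = signed_weight_matrix(p.with_weight("wSS", 0.0))
        expected = np.array(
            [[0.5, -0.5, -0.5], [0.5, -0.5, -0.5], [0.5, -0.5, 0.0]]
        )
        np.testing.assert_allclose(W, expected)

    def test_all_excitatory_identities_keep_magnitudes(self):
        p = CircuitParams(
            weights=np.full((3, 3), 0.3), excitatory=np.array([True] * 3)
        )
        np.testing.assert_allclose(signed_weight_matrix(p), 0.3)

    def test_published_case_row(self):
        p = CircuitParams.from_weights(
            wEE=0.8, wEP=0.5, wPE=1.0, wPP=0.6, wES=0.2
        )
        np.testing.assert_allclose(
            signed_weight_matrix(p),
            [[0.8, -0.5, -0.2], [1.0, -0.6, 0.0], [0.0, 0.0, 0.0]],
        )

    def test_magnitudes_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            CircuitParams(weights=-np.ones((3, 3)))


class TestSimulate:
    def test_decoupled_population_relaxes_exponentially(self, default_params):
        t, r, div = simulate([0, 0, 0], [2.0, 0, 0], default_params, dt=1e-4, T=0.1)
        assert not div
        # tau dr/dt = -r + 1 from rest: r(t) = 1 - exp(-t/tau)
        expected = 1.0 - np.exp(-t / default_params.tau[0])
        assert np.max(np.abs(r[:, 0] - expected)) < 0.01
        assert r[-1, 0] == pytest.approx(1.0, abs=1e-3)

    def test_halving_dt_leaves_fixed_point(self, disinhibitory_params):
        from epvsom import inputs_for_rates

        I = inputs_for_rates([2.0, 3.0, 1.0], disinhibitory_params).I
        ends = []
        for dt in (2e-4, 1e-4):
            _, r, div = simulate([1, 1, 1], I, disinhibitory_params, dt=dt, T=1.0)
            assert not div
            ends.append(r[-1])
        assert np.max(np.abs(ends[0] - ends[1])) < 1e-6

    def test_converged_state_is_self_consistent(self, disinhibitory_params):
        from epvsom import inputs_for_rates
        from epvsom.circuit_model import signed_weight_matrix

        I = inputs_for_rates([2.0, 3.0, 1.0], disinhibitory_params).I
        _, r, _ = simulate([0.5, 0.5, 0.5], I, disinhibitory_params, dt=1e-4, T=2.0)
        Ws = signed_weight_matrix(disinhibitory_params)
        res = r[-1] - transfer(Ws @ r[-1] + I, disinhibitory_params)
        assert np.max(np.abs(res)) < 1e-8

    def test_divergence_is_flagged(self):
        p = CircuitParams.from_weights(wEE=2.0)  # runaway excitation
        with pytest.warns(RuntimeWarning):
            _, _, div = simulate([5, 0, 0], [5.0, 0, 0], p, dt=1e-4, T=0.5)
        assert div

    def test_som_step_disinhibits_E(self):
        """A positive SOM input step raises E rates in the SOM->PV circuit."""
        from epvsom.fixtures import load_fixture

        cfg = load_fixture("fig2a")
        p = cfg.circuit_params()
        from epvsom import inputs_for_rates

        op = inputs_for_rates(cfg.params["rates"], p)

        def drive(t):
            I = op.I.copy()
            if t >= 0.05:
                I[2] += cfg.params["dI_som"]
            return I

        _, r_mod, _ = simulate(op.r, drive, p, dt=1e-4, T=0.3)
        _, r_ref, _ = simulate(op.r, op.I, p, dt=1e-4, T=0.3)
        assert r_mod[-1, 0] > r_ref[-1, 0]

    def test_negative_som_step_with_pv_feedback_lowers_E_and_P(self):
        from epvsom.fixtures import load_fixture
        from epvsom import inputs_for_rates

        cfg = load_fixture("fig2c")
        p = cfg.circuit_params()
        op = inputs_for_rates(cfg.params["rates"], p)

        def drive(t):
            I = op.I.copy()
            if t >= 0.05:
                I[2] += cfg.params["dI_som"]
            return I

        _, r_mod, _ = simulate(op.r, drive, p, dt=1e-4, T=0.3)
        assert r_mod[-1, 0] < op.r[0]
        assert r_mod[-1, 1] < op.r[1]
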