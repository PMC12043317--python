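import numpy as np
import pytest

from epvsom import (
    CircuitParams,
    inputs_for_rates,
    modulation_deltas,
    network_gain,
    network_gain_expanded,
    pathway_expansion,
    pv_response_to_som,
    response_matrix,
    som_to_E_transfer,
    stability,
)
from conftest import random_stable_circuits


class TestResponseMatrix:
    def test_uncoupled_circuit_response_is_cellular_gain(self):
        p = CircuitParams.from_weights()
        op = inputs_for_rates([1.0, 4.0, 2.0], p)
        lr = response_matrix(op, p)
        np.testing.assert_allclose(lr.L, np.diag(op.b), atol=1e-12)

    def test_factorizations_and_jacobian_identity(self):
        for p, op in random_stable_circuits(20, seed=11):
            lr = response_matrix(op, p)
            # L = (-J)^{-1} B with J the rate-dynamics Jacobian BW - 1
            np.testing.assert_allclose(
                lr.L, np.linalg.inv(-lr.J) @ np.diag(op.b), atol=1e-10
            )

    def test_matches_finite_difference_oracle(self, fd_response_matrix):
        for p, op in random_stable_circuits(5, seed=2):
            lr = response_matrix(op, p)
            np.testing.assert_allclose(lr.L, fd_response_matrix(op, p), atol=1e-6)


class TestPathwayExpansion:
    def test_zeroth_order_is_gain_matrix(self, disinhibitory_params):
        op = inputs_for_rates([1.0, 1.0, 1.0], disinhibitory_params)
        sums, rho, conv = pathway_expansion(op, disinhibitory_params, 0)
        np.testing.assert_allclose(sums[0], np.diag(op.b))

    def test_monosynaptic_som_to_E_term(self):
        for p, op in random_stable_circuits(5, seed=3):
            sums, _, _ = pathway_expansion(op, p, 1)
            first_order = sums[1] - sums[0]
            assert first_order[0, 2] == pytest.approx(
                -op.b[0] * op.b[2] * p.weight("wES"), abs=1e-12
            )

    def test_geometric_convergence_to_L(self):
        for p, op in random_stable_circuits(5, seed=4, rho_below_one=True):
            lr = response_matrix(op, p)
            sums, rho, conv = pathway_expansion(op, p, 40)
            assert conv
            errs = [np.abs(s - lr.L).max() for s in sums]
            assert errs[40] < errs[10] < errs[0]
            # average geometric decay rate approaches the spectral radius of
            # BW (per-step ratios oscillate when the leading pair is complex)
            if errs[30] > 1e-14:
                mean_ratio = (errs[30] / errs[10]) ** (1 / 20)
                assert mean_ratio == pytest.approx(rho, rel=0.1)

    def test_divergent_series_flagged(self, disinhibitory_params):
        op = inputs_for_rates([6.0, 6.0, 2.0], disinhibitory_params)
        _, rho, conv = pathway_expansion(op, disinhibitory_params, 5)
        assert rho > 1 and not conv


class TestSomToETransfer:
    def test_disinhibition_raises_E(self, disinhibitory_params):
        op = inputs_for_rates([2.0, 2.0, 2.0], disinhibitory_params)
        L_ES, psi, bracket = som_to_E_transfer(op, disinhibitory_params)
        assert bracket > 0 and L_ES > 0

    def test_direct_inhibition_lowers_E(self):
        p = CircuitParams.from_weights(wEE=0.8, wEP=0.5, wPE=1.0, wPP=0.6, wES=0.2)
        op = inputs_for_rates([2.0, 2.0, 2.0], p)
        L_ES, psi, bracket = som_to_E_transfer(op, p)
        assert bracket < 0 and L_ES < 0

    def test_transfer_equals_response_matrix_element(self):
        for p, op in random_stable_circuits(20, seed=5):
            lr = response_matrix(op, p)
            L_ES, psi, bracket = som_to_E_transfer(op, p)
            assert L_ES == pytest.approx(lr.L[0, 2], abs=1e-10)
            assert psi * bracket == pytest.approx(lr.L[0, 2], abs=1e-10)

    def test_prefactor_positive_when_stable(self):
        for p, op in random_stable_circuits(30, seed=6):
            _, psi, _ = som_to_E_transfer(op, p)
            assert psi > 0

    def test_balanced_pathways_cancel_exactly(self):
        p = CircuitParams.from_weights(wEE=0.4, wEP=0.8, wPE=0.8, wPP=0.5, wPS=0.5)
        op = inputs_for_rates([2.0, 3.0, 1.0], p)
        balanced = p.weight("wEP") * p.weight("wPS") / (1 / op.b[1] + p.weight("wPP"))
        p2 = p.with_weight("wES", balanced)
        op2 = inputs_for_rates([2.0, 3.0, 1.0], p2)
        L_ES, _, _ = som_to_E_transfer(op2, p2)
        assert abs(L_ES) < 1e-10


class TestParadoxicalResponse:
    def test_non_isn_pv_follows_drive(self):
        p = CircuitParams.from_weights(wEE=0.3, wEP=0.8, wPE=0.8, wPP=0.5, wPS=0.5)
        op = inputs_for_rates([1.0, 2.0, 1.0], p)  # bE=1 -> 1/bE=1 > wEE
        L_PS, paradoxical, isn = pv_response_to_som(op, p)
        assert not isn and not paradoxical and L_PS < 0

    def test_isn_pv_response_is_paradoxical(self):
        p = CircuitParams.from_weights(wEE=0.8, wEP=1.0, wPE=1.0, wPP=0.5, wPS=0.5)
        op = inputs_for_rates([4.0, 3.0, 1.0], p)  # bE=2 -> 1/bE=0.5 < wEE
        L_PS, paradoxical, isn = pv_response_to_som(op, p)
        assert isn and paradoxical and L_PS > 0

    def test_zero_recurrent_excitation_never_isn(self):
        p = CircuitParams.from_weights(wEE=0.0, wEP=0.8, wPE=0.8, wPP=0.5, wPS=0.5)
        for rE in (0.5, 4.0, 9.0):
            op = inputs_for_rates([rE, 2.0, 1.0], p)
            _, _, isn = pv_response_to_som(op, p)
            assert not isn


class TestNetworkGain:
    def test_uncoupled_gain_is_cellular_gain(self):
        p = CircuitParams.from_weights()
        op = inputs_for_rates([4.0, 1.0, 1.0], p)
        assert network_gain(op, p, (1.0, 0.0)) == pytest.approx(op.b[0])

    def test_gain_linear_in_stimulus(self, disinhibitory_params):
        op = inputs_for_rates([2.0, 2.0, 1.0], disinhibitory_params)
        g1 = network_gain(op, disinhibitory_params, (1.0, 0.5))
        g2 = network_gain(op, disinhibitory_params, (2.0, 1.0))
        assert g2 == pytest.approx(2 * g1)

    def test_expanded_form_agrees_with_L_elements(self):
        for p, op in random_stable_circuits(20, seed=7):
            g = network_gain(op, p, (1.0, 1.0))
            g_exp = network_gain_expanded(op, p, (1.0, 1.0))
            assert g == pytest.approx(g_exp, abs=1e-10)

    def test_matches_nonlinear_finite_difference(self, disinhibitory_params):
        from conftest import solve_rates_newton

        op = inputs_for_rates([2.0, 2.0, 1.0], disinhibitory_params)
        g = network_gain(op, disinhibitory_params, (1.0, 0.5))
        eps = 1e-5
        dI = np.array([1.0, 0.5, 0.0]) * eps
        r_hi = solve_rates_newton(op.I + dI, disinhibitory_params, op.r)
        r_lo = solve_rates_newton(op.I - dI, disinhibitory_params, op.r)
        assert g == pytest.approx((r_hi[0] - r_lo[0]) / (2 * eps), rel=1e-5)


class TestStability:
    def test_uncoupled_population_decays_at_leak_rate(self):
        p = CircuitParams.from_weights()
        op = inputs_for_rates([2.0, 2.0, 2.0], p)
        lam, eig, osc = stability(op, p)
        np.testing.assert_allclose(sorted(eig.real), [-1, -1, -1])
        assert not osc

    def test_lambda_continuous_except_at_complex_transitions(
        self, disinhibitory_params
    ):
        """Kinks in lambda_max(rP) coincide with real<->complex switches."""
        rPs = np.linspace(0.5, 8, 120)
        lams, oscs = [], []
        for rP in rPs:
            op = inputs_for_rates([3.0, rP, 2.0], disinhibitory_params)
            lam, _, osc = stability(op, disinhibitory_params)
            lams.append(lam)
            oscs.append(osc)
        lams = np.array(lams)
        slopes = np.diff(lams) / np.diff(rPs)
        curvature = np.abs(np.diff(slopes))
        transitions = np.flatnonzero(np.diff(np.array(oscs).astype(int)) != 0)
        assert transitions.size > 0
        # the sharpest kink of lambda_max(rP) sits at a real<->complex switch
        assert np.min(np.abs(int(np.argmax(curvature)) - transitions)) <= 1

    def test_tau_folding_scales_eigenvalues(self, disinhibitory_params):
        op = inputs_for_rates([2.0, 3.0, 1.0], disinhibitory_params)
        lam, eig, _ = stability(op, disinhibitory_params)
        lam_tau, eig_tau, _ = stability(op, disinhibitory_params, include_tau=True)
        np.testing.assert_allclose(
            sorted(eig_tau.real), sorted(eig.real / disinhibitory_params.tau[0])
        )


class TestModulationDeltas:
    def test_zero_modulation_is_identity(self, disinhibitory_params):
        op = inputs_for_rates([2.0, 2.0, 1.0], disinhibitory_params)
        out = modulation_deltas(op, disinhibitory_params, 0.0)
        assert out.delta_g == pytest.approx(0.0, abs=1e-9)
        assert out.delta_lambda == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out.delta_r, 0.0, atol=1e-8)

    def test_linear_and_nonlinear_modes_agree_to_second_order(
        self, disinhibitory_params
    ):
        op = inputs_for_rates([2.0, 2.0, 1.0], disinhibitory_params)
        gaps = []
        for d in (1e-2, 1e-3):
            lin = modulation_deltas(op, disinhibitory_params, d, mode="linear")
            non = modulation_deltas(op, disinhibitory_params, d, mode="nonlinear")
            gaps.append(np.max(np.abs(lin.delta_r - non.delta_r)))
        # O(d^2) scaling: gap shrinks ~100x when d shrinks 10x
        assert gaps[1] < gaps[0] / 50
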