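import numpy as np
import pytest

from epvsom import CircuitParams, inputs_for_rates, response_matrix
from epvsom.circuit_model import signed_weight_matrix, transfer
from epvsom.operating_point import fixed_point


def random_stable_circuits(n, seed=0, rho_below_one=False, max_tries=5000):
    """Sample random E-PV-SOM circuits with a stable operating point.

    Weights are drawn uniformly in ranges that keep the three populations
    recurrently coupled; target rates uniform in [0.5, 6] Hz.  Circuits are
    kept when the operating point is linearizable and strictly stable
    (lambda_max < -0.02); with ``rho_below_one`` also require the pathway
    series to converge (spectral radius of BW < 0.95).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(max_tries):
        if len(out) >= n:
            break
        p = CircuitParams.from_weights(
            wEE=rng.uniform(0, 0.6),
            wEP=rng.uniform(0.3, 1.0),
            wPE=rng.uniform(0.3, 1.0),
            wPP=rng.uniform(0, 0.8),
            wES=rng.uniform(0, 0.8),
            wPS=rng.uniform(0, 0.8),
            wSE=rng.uniform(0, 0.5),
            wSP=rng.uniform(0, 0.5),
        )
        r = rng.uniform(0.5, 6.0, size=3)
        op = inputs_for_rates(r, p)
        lr = response_matrix(op, p)
        if lr.lambda_max >= -0.02:
            continue
        if rho_below_one:
            rho = np.abs(
                np.linalg.eigvals(np.diag(op.b) @ signed_weight_matrix(p))
            ).max()
            if rho >= 0.95:
                continue
        out.append((p, op))
    if len(out) < n:
        raise RuntimeError("could not sample enough stable circuits")
    return out


def solve_rates_newton(I, params, r0, tol=1e-13):
    """Independent high-accuracy solver for r = f(Wr+I).

    Newton iteration with a finite-difference Jacobian (no reuse of the
    package's linearization); used as the oracle when differentiating the
    fixed-point map numerically.
    """
    Ws = signed_weight_matrix(params)

    def g(r):
        return r - transfer(Ws @ r + I, params)

    r = np.asarray(r0, float).copy()
    for _ in range(50):
        val = g(r)
        if np.max(np.abs(val)) < tol:
            return r
        J = np.empty((3, 3))
        h = 1e-7
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            J[:, j] = (g(r + e) - g(r - e)) / (2 * h)
        r = r - np.linalg.solve(J, val)
    return r


@pytest.fixture
def disinhibitory_params():
    """SOM->PV circuit of the motivating example (no feedback onto SOM)."""
    return CircuitParams.from_weights(wEE=0.8, wEP=1.0, wPE=1.0, wPP=0.5, wPS=0.8)


@pytest.fixture
def fd_response_matrix():
    """Finite-difference oracle for the response matrix dr/dI."""

    def _fd(op, params, eps=1e-4):
        L = np.empty((3, 3))
        for j in range(3):
            dI = np.zeros(3)
            dI[j] = eps
            r_hi = solve_rates_newton(op.I + dI, params, op.r)
            r_lo = solve_rates_newton(op.I - dI, params, op.r)
            L[:, j] = (r_hi - r_lo) / (2 * eps)
        return L

    return _fd
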