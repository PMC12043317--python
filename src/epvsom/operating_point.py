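"""Self-consistent network states (operating points).

An operating point is a steady state of the rate dynamics together with the
quantities needed for linearization: rates r, external inputs I, net input
currents q = W r + I (required positive in every population, so the dynamics
sit on the smooth branch of the transfer function), and the cellular gains
b = f'(q).

The forward problem r = f(W r + I) is solved by damped fixed-point iteration;
the backward problem -- which external input puts the network at a *target*
rate vector -- is closed form, I = f^{-1}(r) - W r.  The backward form is the
workhorse of the rate-grid experiments: it parameterizes network states by
their rates, and is valid even where the dynamics around that state are
unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_model import (
    CircuitParams,
    cellular_gain,
    inverse_transfer,
    signed_weight_matrix,
    simulate,
    transfer,
)


class NonConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge (unstable or oscillatory regime)."""

    def __init__(self, msg, diverged=False, residual=np.nan):
        super().__init__(msg)
        self.diverged = diverged
        self.residual = residual


@dataclass(frozen=True)
class OperatingPoint:
    r: np.ndarray  #: population rates (Hz), order (E, P, S)
    I: np.ndarray  #: external inputs
    q: np.ndarray  #: net input currents (positive on the smooth branch)
    b: np.ndarray  #: cellular gains f'(q)

    @property
    def B(self) -> np.ndarray:
        """Diagonal matrix of cellular gains."""
        return np.diag(self.b)

    def residual(self, params: CircuitParams) -> float:
        Ws = signed_weight_matrix(params)
        return float(
            np.max(np.abs(self.r - transfer(Ws @ self.r + self.I, params)))
        )

    def to_record(self) -> dict:
        return {
            "r": self.r.tolist(),
            "I": self.I.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
        }


def _assemble(r: np.ndarray, I: np.ndarray, params: CircuitParams) -> OperatingPoint:
    q = inverse_transfer(r, params)
    zero = q <= 0
    # cellular_gain rejects q<=0; rates exactly 0 keep a gain of 0 so that
    # decoupled silent populations do not block construction (linearization
    # will refuse separately).
    b = np.zeros(3)
    if np.any(~zero):
        b[~zero] = (params.alpha * params.beta * q ** (params.beta - 1.0))[~zero]
    return OperatingPoint(r=np.asarray(r, float), I=np.asarray(I, float), q=q, b=b)


def inputs_for_rates(r_target, params: CircuitParams) -> OperatingPoint:
    """External inputs that place the steady state exactly at ``r_target``.

    Closed form I = f^{-1}(r) - W r; no iteration.  The returned inputs may be
    negative (net hyperpolarizing drive) but the net current q = f^{-1}(r) is
    nonnegative by construction.
    """
    r = np.asarray(r_target, dtype=float)
    if np.any(r < 0):
        raise ValueError("target rates must be nonnegative")
    Ws = signed_weight_matrix(params)
    q = inverse_transfer(r, params)
    I = q - Ws @ r
    return _assemble(r, I, params)


def fixed_point(
    I,
    params: CircuitParams,
    r0=None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    simulate_fallback: bool = True,
) -> OperatingPoint:
    """Solve r = f(W r + I) by damped Picard iteration.

    Robust for rectified power-law maps without derivatives.  Falls back to
    simulating the rate dynamics to convergence if the iteration stalls;
    raises :class:`NonConvergenceError` (with a divergence flag) otherwise.
    """
    I = np.asarray(I, dtype=float)
    Ws = signed_weight_matrix(params)
    r = np.zeros(3) if r0 is None else np.asarray(r0, dtype=float).copy()
    bound = 1e6
    check_every = 200
    last_step = np.inf
    for it in range(max_iter):
        r_new = (1.0 - damping) * r + damping * transfer(Ws @ r + I, params)
        if not np.all(np.isfinite(r_new)) or np.any(np.abs(r_new) > bound):
            raise NonConvergenceError(
                "rate iteration diverged (unstable regime)", diverged=True
            )
        step = np.max(np.abs(r_new - r))
        r = r_new
        if step < tol * damping:
            break
        # stalled iteration: the damped Picard map need not contract even at
        # dynamically stable states -- hand over to the simulation fallback
        # instead of burning the full budget
        if it % check_every == check_every - 1:
            if step > 0.99 * last_step and step > 1e3 * tol:
                break
            last_step = step
    res = np.max(np.abs(r - transfer(Ws @ r + I, params)))
    if res >= tol and simulate_fallback:
        # integrate the rate dynamics in short chunks until the state stops
        # moving; diverging dynamics surface as NonConvergence
        for _ in range(10):
            try:
                _, traj, _ = simulate(
                    r, I, params, dt=params.tau.min() / 10.0, T=0.5,
                    raise_on_divergence=True,
                )
            except Exception as exc:
                raise NonConvergenceError(
                    f"no stable fixed point found ({exc})",
                    diverged=True, residual=res,
                ) from exc
            r = traj[-1]
            res = np.max(np.abs(r - transfer(Ws @ r + I, params)))
            if res < max(tol, 1e-9):
                break
    if res >= max(tol, 1e-8):
        raise NonConvergenceError(
            f"fixed point residual {res:.2e} above tolerance", residual=res
        )
    return _assemble(r, I, params)
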