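"""Three-population (E, PV, SOM) firing-rate circuit.

The circuit is a Wilson-Cowan style rate model

    tau_X dr_X/dt = -r_X + f_X(q_X),    q_X = [sum_Y (+/-) w_XY r_Y + I_X]_+

with a rectified power-law transfer f_X(q) = alpha_X [q]_+**beta_X.
Population order is always (E, P, S).  Synaptic weights are stored as
nonnegative magnitudes; the sign of a column is set by the identity of the
presynaptic population (E excitatory, PV and SOM inhibitory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

POPULATIONS = ("E", "P", "S")

#: weight-name -> (postsynaptic row, presynaptic column) index in the 3x3 matrix
WEIGHT_INDEX = {
    f"w{post}{pre}": (i, j)
    for i, post in enumerate(POPULATIONS)
    for j, pre in enumerate(POPULATIONS)
}


class DivergenceError(RuntimeError):
    """Raised when rate dynamics exceed the divergence bound (unstable regime)."""


def _as_vec3(x, name: str) -> np.ndarray:
    out = np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} must be finite, got {out}")
    return out


@dataclass(frozen=True)
class CircuitParams:
    """Connectivity magnitudes, cell identities and transfer parameters.

    Parameters
    ----------
    weights
        3x3 array of nonnegative synaptic magnitudes ``w[post, pre]`` in
        population order (E, P, S).
    excitatory
        Boolean identity per population; signs of the connectivity columns
        follow from it (default: E excitatory, PV/SOM inhibitory).
    alpha, beta
        Power-law transfer parameters per population, ``f(q)=alpha*q**beta``
        for q > 0.  Defaults 1/4 and 2 for all populations.
    tau
        Rate time constants in seconds (default 10 ms).
    """

    weights: np.ndarray
    excitatory: np.ndarray = field(
        default_factory=lambda: np.array([True, False, False])
    )
    alpha: np.ndarray = field(default_factory=lambda: np.full(3, 0.25))
    beta: np.ndarray = field(default_factory=lambda: np.full(3, 2.0))
    tau: np.ndarray = field(default_factory=lambda: np.full(3, 0.010))

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3, 3):
            raise ValueError(f"weights must be 3x3, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError("synaptic magnitudes must be nonnegative")
        object.__setattr__(self, "weights", w)
        exc = np.broadcast_to(np.asarray(self.excitatory, bool), (3,)).copy()
        object.__setattr__(self, "excitatory", exc)
        for name in ("alpha", "beta", "tau"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name), name))
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive")
        if np.any(self.beta < 1):
            raise ValueError("beta must be >= 1")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")

    @classmethod
    def from_weights(cls, *, wSS: float = 0.0, **kw) -> "CircuitParams":
        """Build params from named magnitudes (``wEE=..., wEP=..., ...``).

        Unnamed couplings default to zero; the SOM self-connection is zero
        unless passed explicitly (SOM->SOM coupling is not observed in
        sensory neocortex and only enters the weight-sweep experiments).
        """
        extra = {k: v for k, v in kw.items() if k not in WEIGHT_INDEX and
                 k not in ("alpha", "beta", "tau", "excitatory")}
        if extra:
            raise ValueError(f"unknown weight/parameter names: {sorted(extra)}")
        w = np.zeros((3, 3))
        w[WEIGHT_INDEX["wSS"]] = wSS
        opts = {}
        for k, v in kw.items():
            if k in WEIGHT_INDEX:
                w[WEIGHT_INDEX[k]] = v
            else:
                opts[k] = v
        return cls(weights=w, **opts)

    def weight(self, name: str) -> float:
        return float(self.weights[WEIGHT_INDEX[name]])

    def with_weight(self, name: str, value: float) -> "CircuitParams":
        """Return a copy with a single coupling magnitude replaced."""
        w = self.weights.copy()
        w[WEIGHT_INDEX[name]] = value
        return replace(self, weights=w)

    def named_weights(self) -> dict:
        return {k: float(self.weights[ij]) for k, ij in WEIGHT_INDEX.items()}


def signed_weight_matrix(params: CircuitParams) -> np.ndarray:
    """Signed connectivity: +w for excitatory presynaptic columns, -w otherwise."""
    signs = np.where(params.excitatory, 1.0, -1.0)
    return params.weights * signs[np.newaxis, :]


def transfer(q, params: CircuitParams) -> np.ndarray:
    """Rectified power-law transfer ``alpha*[q]_+**beta`` (vectorized over q)."""
    q = np.asarray(q, dtype=float)
    return params.alpha * np.clip(q, 0.0, None) ** params.beta


def inverse_transfer(r, params: CircuitParams) -> np.ndarray:
    """Input current producing rate r on the positive branch: ``(r/alpha)**(1/beta)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    return (r / params.alpha) ** (1.0 / params.beta)


def cellular_gain(q, params: CircuitParams) -> np.ndarray:
    """Slope of the transfer function, ``alpha*beta*q**(beta-1)``, at input q > 0.

    The linearization is undefined at the rectification kink, so nonpositive
    inputs raise: an operating point with q <= 0 in any population cannot be
    linearized.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        bad = [POPULATIONS[i] for i in np.atleast_1d(np.argwhere(q <= 0)).ravel()]
        raise ValueError(
            f"cellular gain undefined at q<=0 (rectification kink); populations {bad}"
        )
    return params.alpha * params.beta * q ** (params.beta - 1.0)


def simulate(
    r0,
    I,
    params: CircuitParams,
    dt: float = 1e-4,
    T: float = 1.0,
    divergence_bound: float = 1e6,
    raise_on_divergence: bool = False,
):
    """Forward-Euler integration of the rate dynamics.

    Parameters
    ----------
    r0 : initial rates (3,)
    I : external input; a (3,) constant, an array of shape (n_steps, 3), or a
        callable ``I(t) -> (3,)`` (step changes in input are allowed).
    dt, T : timestep and duration in seconds.
    divergence_bound : abort once any rate exceeds this bound (unstable regime).

    Returns
    -------
    t : (n+1,) times, r : (n+1, 3) rate trajectory, diverged : bool
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    Ws = signed_weight_matrix(params)
    if callable(I):
        get_I = I
    else:
        I_arr = np.asarray(I, dtype=float)
        if I_arr.ndim == 1:
            get_I = lambda tt: I_arr  # noqa: E731
        else:
            if I_arr.shape != (n, 3) and I_arr.shape != (n + 1, 3):
                raise ValueError("input time course must have shape (n_steps, 3)")
            get_I = lambda tt: I_arr[min(int(round(tt / dt)), len(I_arr) - 1)]  # noqa: E731

    r = np.empty((n + 1, 3))
    r[0] = np.asarray(r0, dtype=float)
    coeff = dt / params.tau
    diverged = False
    for k in range(n):
        drive = transfer(Ws @ r[k] + np.asarray(get_I(t[k]), dtype=float), params)
        r[k + 1] = r[k] + coeff * (drive - r[k])
        if np.any(np.abs(r[k + 1]) > divergence_bound) or not np.all(
            np.isfinite(r[k + 1])
        ):
            diverged = True
            r = r[: k + 2]
            t = t[: k + 2]
            break
    if diverged and raise_on_divergence:
        raise DivergenceError(
            f"rates exceeded divergence bound {divergence_bound:g} at t={t[-1]:.4f}s"
        )
    if diverged:
        warnings.warn("simulation diverged (unstable regime)", RuntimeWarning)
    return t, r, diverged


def trajectory_frame(t: np.ndarray, r: np.ndarray):
    """Tidy trajectory table with columns t, rE, rP, rS."""
    import pandas as pd

    return pd.DataFrame({"t": t, "rE": r[:, 0], "rP": r[:, 1], "rS": r[:, 2]})
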