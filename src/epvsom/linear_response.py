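"""Linearized response of the E-PV-SOM circuit around an operating point.

Everything here follows from two matrices evaluated at a self-consistent
state: the signed connectivity W and the diagonal cellular-gain matrix
B = diag(b).  The response matrix

    L = (B^{-1} - W)^{-1} = (1 - B W)^{-1} B = (-J)^{-1},   J = W - B^{-1},

maps small steady external-input perturbations to steady rate changes.  The
module exposes:

* the response matrix with both factorizations cross-checked,
* the synaptic-pathway (Neumann-series) expansion L = sum_i (BW)^i B,
* the SOM->E transfer split into a positive prefactor times the
  inhibitory/disinhibitory "bracket" motif,
* the PV response to SOM modulation (paradoxical-response / ISN criterion),
* the E-population network gain for stimuli onto E and PV,
* eigenvalue stability (largest real part of J) and
* before/after deltas of gain and stability under a SOM modulation.

Stability uses the Jacobian of the rate dynamics in units of the common time
constant, J = B W - 1 (the linearization of tau dr/dt = -r + f(Wr+I)), so
that eigenvalue real parts are actual decay/growth rates of the dynamics and
L = (-J)^{-1} B.  The superficially similar matrix W - B^{-1} = B^{-1} J
shares the determinant-sign (saddle-node) boundary with J but *not* its
oscillatory (Hopf) instabilities, and so misclassifies dynamically unstable
states; it is not used for stability here.  Set ``include_tau=True`` to fold
in T^{-1} when time constants differ across populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .circuit_model import CircuitParams, signed_weight_matrix
from .operating_point import (
    NonConvergenceError,
    OperatingPoint,
    fixed_point,
    inputs_for_rates,
)

__all__ = [
    "LinearResponse",
    "ModulationOutcome",
    "SingularMatrixError",
    "response_matrix",
    "pathway_expansion",
    "som_to_E_transfer",
    "pv_response_to_som",
    "network_gain",
    "stability",
    "modulation_deltas",
]

DEFAULT_STIMULUS = (1.0, 1.0)  # equal unit drive onto E and PV


class SingularMatrixError(np.linalg.LinAlgError):
    """B^{-1} - W is numerically singular (an eigenvalue is crossing zero)."""


def _check_linearizable(op: OperatingPoint):
    if np.any(op.q <= 0) or np.any(op.b <= 0):
        from .circuit_model import POPULATIONS

        bad = [POPULATIONS[i] for i in np.flatnonzero(op.q <= 0)]
        raise ValueError(
            f"cannot linearize: net current q<=0 in population(s) {bad} "
            "(operating point sits on the rectified branch)"
        )


@dataclass(frozen=True)
class LinearResponse:
    L: np.ndarray
    J: np.ndarray
    eigenvalues: np.ndarray
    lambda_max: float
    is_stable: bool
    is_oscillatory: bool

    def to_record(self) -> dict:
        return {
            "axes": ["E", "P", "S"],
            "L": self.L.tolist(),
            "J": self.J.tolist(),
            "eigenvalues_real": self.eigenvalues.real.tolist(),
            "eigenvalues_imag": self.eigenvalues.imag.tolist(),
            "lambda_max": self.lambda_max,
            "is_stable": self.is_stable,
            "is_oscillatory": self.is_oscillatory,
        }


@dataclass(frozen=True)
class ModulationOutcome:
    delta_I_som: float
    delta_r: np.ndarray
    gE_before: float
    gE_after: float
    delta_g: float
    delta_lambda: float
    op_before: OperatingPoint
    op_after: OperatingPoint


def stability(op: OperatingPoint, params: CircuitParams, include_tau: bool = False):
    """Eigenvalue stability of the linearized dynamics.

    Returns ``(lambda_max, eigenvalues, is_oscillatory)`` where lambda_max is
    the largest real part of the eigenvalues of J = B W - 1 (per unit tau)
    and the oscillatory flag marks a complex leading eigenvalue (it explains
    apparent discontinuities of lambda_max along parameter sweeps, where the
    leading eigenvalue switches or a complex pair collides with the real
    axis).
    """
    _check_linearizable(op)
    Ws = signed_weight_matrix(params)
    J = np.diag(op.b) @ Ws - np.eye(3)
    if include_tau:
        J = np.diag(1.0 / params.tau) @ J
    eig = np.linalg.eigvals(J)
    lead = int(np.argmax(eig.real))
    return float(eig.real.max()), eig, bool(abs(eig[lead].imag) > 1e-12)


def response_matrix(
    op: OperatingPoint, params: CircuitParams, cross_check_tol: float = 1e-8
) -> LinearResponse:
    """Response matrix L with both factorizations computed and cross-checked."""
    _check_linearizable(op)
    Ws = signed_weight_matrix(params)
    B = np.diag(op.b)
    Binv = np.diag(1.0 / op.b)
    M = Binv - Ws
    if abs(np.linalg.det(M)) < 1e-12:
        raise SingularMatrixError(
            "B^-1 - W is singular: operating point is marginally stable"
        )
    L1 = np.linalg.inv(M)
    L2 = np.linalg.solve(np.eye(3) - B @ Ws, B)
    scale = max(1.0, np.abs(L1).max())
    if np.abs(L1 - L2).max() > cross_check_tol * scale:
        raise FloatingPointError("factorizations of the response matrix disagree")
    J = B @ Ws - np.eye(3)
    eig = np.linalg.eigvals(J)
    lam = float(eig.real.max())
    lead = int(np.argmax(eig.real))
    return LinearResponse(
        L=L1,
        J=J,
        eigenvalues=eig,
        lambda_max=lam,
        is_stable=lam < 0,
        is_oscillatory=bool(abs(eig[lead].imag) > 1e-12),
    )


def pathway_expansion(op: OperatingPoint, params: CircuitParams, max_order: int):
    """Partial sums of the synaptic-pathway series L = sum_i (BW)^i B.

    Returns ``(partial_sums, spectral_radius, converges)`` where
    ``partial_sums[k] = sum_{i<=k} (BW)^i B``.  The series converges to L iff
    the spectral radius of BW is below one; a divergent series is still
    returned, flagged False.
    """
    _check_linearizable(op)
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    Ws = signed_weight_matrix(params)
    B = np.diag(op.b)
    BW = B @ Ws
    rho = float(np.abs(np.linalg.eigvals(BW)).max())
    term = B.copy()
    acc = B.copy()
    sums = [acc.copy()]
    for _ in range(max_order):
        term = BW @ term
        acc = acc + term
        sums.append(acc.copy())
    return sums, rho, rho < 1.0


def _det_M(op: OperatingPoint, params: CircuitParams) -> float:
    Ws = signed_weight_matrix(params)
    return float(np.linalg.det(np.diag(1.0 / op.b) - Ws))


def som_to_E_transfer(op: OperatingPoint, params: CircuitParams):
    """SOM->E transfer L_ES as prefactor times pathway bracket.

    L_ES = psi_ES * bracket with

        psi_ES = (bP^-1 + wPP) / det(B^-1 - W)           (positive when stable)
        bracket = wEP*wPS / (bP^-1 + wPP) - wES

    The bracket weighs the disinhibitory motif (SOM->PV->E, discounted by PV
    self-inhibition and leak) against the direct inhibitory motif (SOM->E); its
    sign is the sign of the E-rate response to a positive SOM modulation.
    Returns ``(L_ES, psi_ES, bracket)``.
    """
    _check_linearizable(op)
    w = params.named_weights()
    bP = op.b[1]
    denom = 1.0 / bP + w["wPP"]
    psi = denom / _det_M(op, params)
    bracket = w["wEP"] * w["wPS"] / denom - w["wES"]
    return psi * bracket, psi, bracket


def pv_response_to_som(op: OperatingPoint, params: CircuitParams):
    """PV response to SOM modulation: L_PS, paradoxical flag, ISN flag.

    L_PS = ((wEE - bE^-1) wPS - wES wPE) / det(B^-1 - W).  With no direct
    SOM->E coupling the sign of L_PS flips exactly at the ISN boundary
    wEE = 1/bE: in the ISN regime a positive SOM modulation (which withdraws
    drive from PV) *increases* the PV rate -- the paradoxical response.
    """
    _check_linearizable(op)
    w = params.named_weights()
    bE = op.b[0]
    L_PS = ((w["wEE"] - 1.0 / bE) * w["wPS"] - w["wES"] * w["wPE"]) / _det_M(
        op, params
    )
    return L_PS, L_PS > 0, w["wEE"] > 1.0 / bE


def network_gain(
    op: OperatingPoint,
    params: CircuitParams,
    dI_stim: Sequence[float] = DEFAULT_STIMULUS,
) -> float:
    """E-population network gain for a stimulus onto E and PV.

    gE = L_EE dIE + L_EP dIP: the steady E-rate change per unit stimulus,
    routed through the full recurrent circuit (as opposed to the cellular
    gain bE of the E transfer function alone).
    """
    lr = response_matrix(op, params)
    dIE, dIP = float(dI_stim[0]), float(dI_stim[1])
    return float(lr.L[0, 0] * dIE + lr.L[0, 1] * dIP)


def network_gain_expanded(
    op: OperatingPoint,
    params: CircuitParams,
    dI_stim: Sequence[float] = DEFAULT_STIMULUS,
) -> float:
    """Closed-form network gain (valid for wSS = 0); cross-check of network_gain.

    gE = psi_g [((bP^-1 + wPP) - bS wPS wSP) dIE - (wEP - bS wES wSP) dIP],
    psi_g = bS^-1 / det(B^-1 - W) > 0 when stable.
    """
    w = params.named_weights()
    if w["wSS"] != 0.0:
        raise ValueError("closed form assumes wSS = 0")
    bP, bS = op.b[1], op.b[2]
    psi_g = (1.0 / bS) / _det_M(op, params)
    dIE, dIP = float(dI_stim[0]), float(dI_stim[1])
    return float(
        psi_g
        * (
            ((1.0 / bP + w["wPP"]) - bS * w["wPS"] * w["wSP"]) * dIE
            - (w["wEP"] - bS * w["wES"] * w["wSP"]) * dIP
        )
    )


def modulation_deltas(
    op: OperatingPoint,
    params: CircuitParams,
    dI_som: float,
    dI_stim: Sequence[float] = DEFAULT_STIMULUS,
    mode: Literal["linear", "nonlinear"] = "nonlinear",
) -> ModulationOutcome:
    """Gain and stability changes induced by a SOM input modulation.

    The modulated state is obtained either by the linear map
    delta_r = L (0, 0, dI_som) or by re-solving the nonlinear fixed point at
    I + (0, 0, dI_som) (default, matching forward simulation).  Both gain and
    stability deltas are computed between the same pre/post operating points:

        delta_g      = gE(mod) - gE
        delta_lambda = lambda_max - lambda_max(mod)   (>0: stability increased)
    """
    lr = response_matrix(op, params)
    g_before = float(lr.L[0, 0] * dI_stim[0] + lr.L[0, 1] * dI_stim[1])
    dI = np.array([0.0, 0.0, float(dI_som)])
    if mode == "linear":
        r_after = op.r + lr.L @ dI
        if np.any(r_after < 0):
            raise NonConvergenceError("linearly modulated rates became negative")
        op_after = inputs_for_rates(r_after, params)
        # keep the actual modulated inputs for the record
        op_after = OperatingPoint(
            r=op_after.r, I=op.I + dI, q=op_after.q, b=op_after.b
        )
    elif mode == "nonlinear":
        guess = np.clip(op.r + lr.L @ dI, 0.0, None)
        op_after = fixed_point(op.I + dI, params, r0=guess)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lr_after = response_matrix(op_after, params)
    g_after = float(lr_after.L[0, 0] * dI_stim[0] + lr_after.L[0, 1] * dI_stim[1])
    return ModulationOutcome(
        delta_I_som=float(dI_som),
        delta_r=op_after.r - op.r,
        gE_before=g_before,
        gE_after=g_after,
        delta_g=g_after - g_before,
        delta_lambda=lr.lambda_max - lr_after.lambda_max,
        op_before=op,
        op_after=op_after,
    )
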