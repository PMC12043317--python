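"""Grid, vector-field and weight-sweep experiments.

The central device is the rate grid: network states are parameterized by their
(rE, rP) rates at a fixed SOM rate, with the external inputs recomputed in
closed form at every cell.  Gain and stability are therefore defined at every
grid point -- including cells where the rate dynamics are unstable, which are
only masked, not skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit_model import WEIGHT_INDEX, CircuitParams
from .linear_response import (
    DEFAULT_STIMULUS,
    modulation_deltas,
    network_gain,
    response_matrix,
)
from .operating_point import NonConvergenceError, inputs_for_rates

DEFAULT_RATE_AXIS = np.linspace(0.5, 10.0, 50)

#: quadrant labels by sign pattern of (delta_g, delta_lambda); the mapping is a
#: package convention -- prefer the explicit sign keys when reading results.
QUADRANTS = {
    "Q1": (1, 1),    # gain up, stability up
    "Q2": (-1, 1),   # gain down, stability up
    "Q3": (-1, -1),  # gain down, stability down
    "Q4": (1, -1),   # gain up, stability down
}


@dataclass
class GridScan:
    rE_axis: np.ndarray
    rP_axis: np.ndarray
    rS: float
    gain: np.ndarray          # [iE, iP]
    lam: np.ndarray
    isn_mask: np.ndarray
    unstable_mask: np.ndarray
    oscillatory_mask: np.ndarray
    dI_stim: tuple

    @property
    def gain_norm(self) -> np.ndarray:
        """Gain divided by the maximum absolute finite value over the grid."""
        m = np.nanmax(np.abs(self.gain))
        return self.gain / m if m > 0 else self.gain

    @property
    def lambda_norm(self) -> np.ndarray:
        """lambda_max mapped by lambda/|min lambda| (most stable cell -> -1)."""
        m = abs(np.nanmin(self.lam))
        return self.lam / m if m > 0 else self.lam

    def to_frame(self) -> pd.DataFrame:
        iE, iP = np.meshgrid(
            np.arange(self.rE_axis.size), np.arange(self.rP_axis.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "rE": self.rE_axis[iE.ravel()],
                "rP": self.rP_axis[iP.ravel()],
                "rS": self.rS,
                "gain": self.gain.ravel(),
                "lambda": self.lam.ravel(),
                "gain_norm": self.gain_norm.ravel(),
                "lambda_norm": self.lambda_norm.ravel(),
                "isn": self.isn_mask.ravel(),
                "unstable": self.unstable_mask.ravel(),
                "oscillatory": self.oscillatory_mask.ravel(),
            }
        )


@dataclass
class VectorField:
    scan: GridScan
    dI_som: float
    arrows: np.ndarray       # [iE, iP, 2], unit-norm (d_rE, d_rP); NaN if masked
    delta_rE: np.ndarray
    delta_rP: np.ndarray
    delta_g: np.ndarray
    delta_lambda: np.ndarray
    converged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.scan.to_frame()
        df["d_rE"] = self.delta_rE.ravel()
        df["d_rP"] = self.delta_rP.ravel()
        df["arrow_rE"] = self.arrows[..., 0].ravel()
        df["arrow_rP"] = self.arrows[..., 1].ravel()
        df["d_g"] = self.delta_g.ravel()
        df["d_lambda"] = self.delta_lambda.ravel()
        df["converged"] = self.converged.ravel()
        return df


@dataclass
class SweepResult:
    weight_name: str
    values: np.ndarray
    gain: np.ndarray
    lam: np.ndarray
    oscillatory: np.ndarray
    fixed_rates: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "weight": self.weight_name,
                "value": self.values,
                "gain": self.gain,
                "lambda": self.lam,
                "oscillatory": self.oscillatory,
                "rE": self.fixed_rates[0],
                "rP": self.fixed_rates[1],
                "rS": self.fixed_rates[2],
            }
        )


def rate_grid_scan(
    params: CircuitParams,
    rE_axis: Sequence[float] = DEFAULT_RATE_AXIS,
    rP_axis: Sequence[float] = DEFAULT_RATE_AXIS,
    rS: float = 2.0,
    dI_stim: Sequence[float] = DEFAULT_STIMULUS,
) -> GridScan:
    """Network gain and stability over an (rE, rP) grid at fixed SOM rate."""
    rE_axis = np.asarray(rE_axis, float)
    rP_axis = np.asarray(rP_axis, float)
    for ax, name in ((rE_axis, "rE_axis"), (rP_axis, "rP_axis")):
        if np.any(ax <= 0) or np.any(np.diff(ax) <= 0):
            raise ValueError(f"{name} must be strictly positive and increasing")
    nE, nP = rE_axis.size, rP_axis.size
    gain = np.empty((nE, nP))
    lam = np.empty((nE, nP))
    isn = np.empty((nE, nP), bool)
    osc = np.empty((nE, nP), bool)
    wEE = params.weight("wEE")
    for i, rE in enumerate(rE_axis):
        for j, rP in enumerate(rP_axis):
            op = inputs_for_rates([rE, rP, rS], params)
            lr = response_matrix(op, params)
            gain[i, j] = lr.L[0, 0] * dI_stim[0] + lr.L[0, 1] * dI_stim[1]
            lam[i, j] = lr.lambda_max
            osc[i, j] = lr.is_oscillatory
            isn[i, j] = wEE > 1.0 / op.b[0]
    return GridScan(
        rE_axis=rE_axis,
        rP_axis=rP_axis,
        rS=float(rS),
        gain=gain,
        lam=lam,
        isn_mask=isn,
        unstable_mask=lam >= 0,
        oscillatory_mask=osc,
        dI_stim=tuple(dI_stim),
    )


def modulation_vector_field(
    params: CircuitParams,
    scan: GridScan,
    dI_som: float,
    mode: str = "nonlinear",
) -> VectorField:
    """Per-cell modulated state: rate-change arrows plus (delta_g, delta_lambda).

    Arrows are the (d_rE, d_rP) direction normalized to unit length; cells
    whose modulated state fails to converge are masked (NaN, converged=False).
    """
    if dI_som == 0:
        raise ValueError("modulation amplitude must be nonzero")
    nE, nP = scan.rE_axis.size, scan.rP_axis.size
    shape = (nE, nP)
    d_rE = np.full(shape, np.nan)
    d_rP = np.full(shape, np.nan)
    d_g = np.full(shape, np.nan)
    d_l = np.full(shape, np.nan)
    ok = np.zeros(shape, bool)
    for i, rE in enumerate(scan.rE_axis):
        for j, rP in enumerate(scan.rP_axis):
            op = inputs_for_rates([rE, rP, scan.rS], params)
            try:
                out = modulation_deltas(
                    op, params, dI_som, dI_stim=scan.dI_stim, mode=mode
                )
            except (NonConvergenceError, ValueError):
                continue
            d_rE[i, j], d_rP[i, j] = out.delta_r[0], out.delta_r[1]
            d_g[i, j] = out.delta_g
            d_l[i, j] = out.delta_lambda
            ok[i, j] = True
    arrows = np.stack([d_rE, d_rP], axis=-1)
    norms = np.linalg.norm(arrows, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        arrows = np.where(norms > 0, arrows / norms, np.nan)
    return VectorField(
        scan=scan,
        dI_som=float(dI_som),
        arrows=arrows,
        delta_rE=d_rE,
        delta_rP=d_rP,
        delta_g=d_g,
        delta_lambda=d_l,
        converged=ok,
    )


def quadrant_statistics(
    field: VectorField,
    g_threshold: float = 0.1,
    lambda_threshold: float = 0.01,
) -> dict:
    """Percentage of grid cells per (delta_g, delta_lambda) sign quadrant.

    Cells with |delta_g| <= g_threshold or |delta_lambda| <= lambda_threshold
    are excluded; percentages are over the included cells and sum to 100.
    With no included cells the percentages are undefined (NaN).
    """
    dg = field.delta_g.ravel()
    dl = field.delta_lambda.ravel()
    keep = (
        field.converged.ravel()
        & (np.abs(dg) > g_threshold)
        & (np.abs(dl) > lambda_threshold)
    )
    n = int(keep.sum())
    out = {"n_included": n}
    for label, (sg, sl) in QUADRANTS.items():
        if n == 0:
            out[label] = np.nan
        else:
            out[label] = 100.0 * np.sum(
                keep & (np.sign(dg) == sg) & (np.sign(dl) == sl)
            ) / n
        out[f"{label}_signs"] = {"delta_g": QUADRANTS[label][0],
                                 "delta_lambda": QUADRANTS[label][1]}
    return out


def weight_sweep(
    params: CircuitParams,
    weight_name: str,
    values: Sequence[float],
    fixed_rates: Sequence[float] = (3.0, 5.0, 0.5),
    dI_stim: Sequence[float] = DEFAULT_STIMULUS,
) -> SweepResult:
    """Gain and stability as one synaptic magnitude varies at pinned rates.

    At every sweep value the external inputs are recomputed so the operating
    point keeps exactly ``fixed_rates``; changes in gain/stability are then
    purely synaptic, not rate-mediated.
    """
    if weight_name not in WEIGHT_INDEX:
        raise ValueError(f"unknown weight {weight_name!r}")
    fixed_rates = np.asarray(fixed_rates, float)
    if np.any(fixed_rates <= 0):
        raise ValueError("fixed rates must be positive")
    values = np.asarray(values, float)
    gain = np.empty(values.size)
    lam = np.empty(values.size)
    osc = np.empty(values.size, bool)
    for k, v in enumerate(values):
        p = params.with_weight(weight_name, v)
        op = inputs_for_rates(fixed_rates, p)
        lr = response_matrix(op, p)
        gain[k] = lr.L[0, 0] * dI_stim[0] + lr.L[0, 1] * dI_stim[1]
        lam[k] = lr.lambda_max
        osc[k] = lr.is_oscillatory
    return SweepResult(
        weight_name=weight_name,
        values=values,
        gain=gain,
        lam=lam,
        oscillatory=osc,
        fixed_rates=tuple(fixed_rates),
    )
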