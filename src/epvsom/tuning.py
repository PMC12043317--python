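"""Tuned-stimulus experiments and additive/multiplicative modulation arithmetic.

The stimulus is parameterized by an angle theta in [0, 180] degrees and enters
E and PV (identically) with a Gaussian tuning profile; SOM receives only
untuned background input, so any SOM tuning is inherited through E->SOM
feedback.  A SOM modulation changes the tuning curves of all populations; the
change is summarized, as in optogenetic studies, by regressing modulated on
unmodulated rates: slope > 1 multiplicative / < 1 divisive, intercept > 0
additive / < 0 subtractive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit_model import CircuitParams
from .operating_point import NonConvergenceError, fixed_point

DEFAULT_THETA_AXIS = np.arange(0.0, 181.0, 1.0)
DEFAULT_BACKGROUND = (1.0, 1.0, 1.5)


def tuned_stimulus(
    theta: float,
    wff: float = 2.0,
    theta_p: float = 90.0,
    sigma_theta: float = 20.0,
) -> np.ndarray:
    """Gaussian feedforward drive at angle theta: wff*exp(-(theta-theta_p)^2/sigma^2)*(1,1,0)."""
    theta = np.asarray(theta, float)
    profile = wff * np.exp(-((theta - theta_p) ** 2) / sigma_theta**2)
    return np.multiply.outer(profile, np.array([1.0, 1.0, 0.0]))


@dataclass
class TuningExperiment:
    theta_axis: np.ndarray
    curves_pre: np.ndarray   # (n_theta, 3) fixed-point rates, unmodulated
    curves_post: np.ndarray  # (n_theta, 3) with SOM modulation
    converged: np.ndarray    # (n_theta,) both conditions converged
    dI_som: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"theta": self.theta_axis})
        for i, pop in enumerate("EPS"):
            df[f"r{pop}_pre"] = self.curves_pre[:, i]
            df[f"r{pop}_post"] = self.curves_post[:, i]
        df["converged"] = self.converged
        return df


@dataclass
class LinearDecomposition:
    slope: float
    intercept: float
    intercept_norm: float  #: intercept / max unmodulated rate of that population
    scaling: str           #: "multiplicative" | "divisive" | "none"
    shift: str             #: "additive" | "subtractive" | "none"

    @property
    def classification(self) -> str:
        return f"{self.scaling}+{self.shift}"


def tuning_modulation_experiment(
    params: CircuitParams,
    dI_som: float,
    Iback: Sequence[float] = DEFAULT_BACKGROUND,
    theta_axis: Sequence[float] = DEFAULT_THETA_AXIS,
    wff: float = 2.0,
    theta_p: float = 90.0,
    sigma_theta: float = 20.0,
) -> TuningExperiment:
    """Tuning curves of all populations before and after SOM modulation.

    At each angle the steady state is solved for I = Iback + Istim(theta),
    and again with the SOM modulation (0, 0, dI_som) added.  Angles where
    either solve fails to converge are masked (NaN) and flagged.
    """
    theta_axis = np.asarray(theta_axis, float)
    Iback = np.asarray(Iback, float)
    mod = np.array([0.0, 0.0, float(dI_som)])
    pre = np.full((theta_axis.size, 3), np.nan)
    post = np.full((theta_axis.size, 3), np.nan)
    ok = np.zeros(theta_axis.size, bool)
    guess_pre = guess_post = None
    for k, th in enumerate(theta_axis):
        I = Iback + tuned_stimulus(th, wff, theta_p, sigma_theta)
        try:
            op0 = fixed_point(I, params, r0=guess_pre)
            op1 = fixed_point(I + mod, params, r0=guess_post)
        except NonConvergenceError:
            guess_pre = guess_post = None
            continue
        pre[k] = op0.r
        post[k] = op1.r
        guess_pre, guess_post = op0.r, op1.r  # warm start along the theta axis
        ok[k] = True
    return TuningExperiment(
        theta_axis=theta_axis,
        curves_pre=pre,
        curves_post=post,
        converged=ok,
        dI_som=float(dI_som),
    )


def decompose_linear(
    curve_pre: Sequence[float], curve_post: Sequence[float]
) -> LinearDecomposition:
    """OLS regression of modulated on unmodulated rates.

    Classification: slope > 1 multiplicative, slope < 1 divisive; intercept
    > 0 additive, < 0 subtractive.  The normalized intercept divides by the
    maximum of the unmodulated curve.  A constant pre curve leaves the slope
    undefined and is rejected.
    """
    pre = np.asarray(curve_pre, float)
    post = np.asarray(curve_post, float)
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    if pre.size < 3:
        raise ValueError("need at least 3 finite points to fit")
    if np.ptp(pre) < 1e-12:
        raise ValueError("constant unmodulated curve: slope undefined")
    fit = stats.linregress(pre, post)
    slope, intercept = float(fit.slope), float(fit.intercept)
    tol = 1e-9
    scaling = "multiplicative" if slope > 1 + tol else (
        "divisive" if slope < 1 - tol else "none")
    shift = "additive" if intercept > tol else (
        "subtractive" if intercept < -tol else "none")
    return LinearDecomposition(
        slope=slope,
        intercept=intercept,
        intercept_norm=intercept / pre.max(),
        scaling=scaling,
        shift=shift,
    )


def decompose_experiment(exp: TuningExperiment) -> dict:
    """Per-population linear decomposition of a tuning experiment."""
    return {
        pop: decompose_linear(exp.curves_pre[:, i], exp.curves_post[:, i])
        for i, pop in enumerate("EPS")
    }
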