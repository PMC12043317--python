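"""Execute an :class:`~epvsom.config.ExperimentConfig` and write artifacts.

Each experiment writes a tidy CSV (where tabular output exists) plus a JSON
summary, and returns the summary dict.  Outputs are deterministic given the
config and seed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import scans, stochastic, tuning
from .circuit_model import simulate, trajectory_frame
from .config import ExperimentConfig, _plain
from .linear_response import modulation_deltas, network_gain, response_matrix
from .operating_point import inputs_for_rates


def run_config(config: ExperimentConfig, out_dir, seed: int | None = None) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    params = config.circuit_params()
    seed = config.seed if seed is None else int(seed)
    runner = _RUNNERS[config.experiment]
    summary = runner(config, params, out_dir, seed)
    summary["experiment"] = config.experiment
    summary["name"] = config.name
    summary["seed"] = seed
    summary["runtime_s"] = round(time.time() - t0, 3)
    (out_dir / "summary.json").write_text(json.dumps(_plain(summary), indent=2))
    config.save(out_dir / "config.json")
    return summary


def _run_simulate(config, params, out_dir, seed):
    p = config.params
    rates = np.asarray(p["rates"], float)
    op = inputs_for_rates(rates, params)
    dI_som = float(p.get("dI_som", 0.0))
    dI_stim = np.asarray(p.get("dI_stim", [0.0, 0.0]), float)
    t_mod, t_stim = p.get("t_mod", 0.05), p.get("t_stim", 0.35)
    dt, T = p.get("dt", 1e-4), p.get("T", 0.6)

    def drive(mod):
        def I(t):
            out = op.I.copy()
            if mod and t >= t_mod:
                out[2] += dI_som
            if t >= t_stim:
                out[:2] += dI_stim
            return out
        return I

    r0 = np.asarray(p.get("r0", rates), float)
    t, r_mod, div1 = simulate(r0, drive(True), params, dt=dt, T=T)
    _, r_ref, div2 = simulate(r0, drive(False), params, dt=dt, T=T)
    frame = trajectory_frame(t, r_mod)
    for i, pop in enumerate("EPS"):
        frame[f"r{pop}_unmod"] = r_ref[: len(t), i]
    frame.to_csv(out_dir / "trajectory.csv", index=False)
    summary = {"diverged": bool(div1 or div2), "rates_target": rates.tolist()}
    if dI_som != 0.0:
        out = modulation_deltas(op, params, dI_som, dI_stim=tuple(dI_stim)
                                if dI_stim.any() else (1.0, 1.0))
        summary.update(
            delta_g=out.delta_g,
            delta_lambda=out.delta_lambda,
            gE=out.gE_before,
            gE_mod=out.gE_after,
            delta_rE=out.delta_r[0],
        )
    return summary


def _run_scan(config, params, out_dir, seed):
    p = config.params
    scan = scans.rate_grid_scan(
        params,
        rE_axis=np.asarray(p.get("rE_axis", scans.DEFAULT_RATE_AXIS)),
        rP_axis=np.asarray(p.get("rP_axis", scans.DEFAULT_RATE_AXIS)),
        rS=p.get("rS", 2.0),
        dI_stim=p.get("dI_stim", (1.0, 1.0)),
    )
    scan.to_frame().to_csv(out_dir / "scan.csv", index=False)
    return {
        "gain_max": float(np.nanmax(scan.gain)),
        "gain_min": float(np.nanmin(scan.gain)),
        "lambda_min": float(np.nanmin(scan.lam)),
        "lambda_max": float(np.nanmax(scan.lam)),
        "unstable_fraction": float(scan.unstable_mask.mean()),
        "isn_fraction": float(scan.isn_mask.mean()),
    }


def _run_vectorfield(config, params, out_dir, seed):
    p = config.params
    scan = scans.rate_grid_scan(
        params,
        rE_axis=np.asarray(p.get("rE_axis", scans.DEFAULT_RATE_AXIS)),
        rP_axis=np.asarray(p.get("rP_axis", scans.DEFAULT_RATE_AXIS)),
        rS=p.get("rS", 2.0),
        dI_stim=p.get("dI_stim", (1.0, 1.0)),
    )
    field = scans.modulation_vector_field(params, scan, p["dI_som"])
    field.to_frame().to_csv(out_dir / "vectorfield.csv", index=False)
    stats = scans.quadrant_statistics(
        field,
        g_threshold=p.get("g_threshold", 0.1),
        lambda_threshold=p.get("lambda_threshold", 0.01),
    )
    return {"quadrants": {k: v for k, v in stats.items() if not k.endswith("_signs")},
            "converged_fraction": float(field.converged.mean())}


def _run_sweep(config, params, out_dir, seed):
    import pandas as pd

    p = config.params
    frames = []
    summary = {}
    for wname in p["weights"]:
        res = scans.weight_sweep(
            params, wname, np.asarray(p["values"], float),
            fixed_rates=p.get("fixed_rates", (3.0, 5.0, 0.5)),
            dI_stim=p.get("dI_stim", (1.0, 1.0)),
        )
        frames.append(res.to_frame())
        summary[wname] = {
            "gain_range": float(res.gain.max() - res.gain.min()),
            "lambda_range": float(res.lam.max() - res.lam.min()),
        }
    pd.concat(frames, ignore_index=True).to_csv(out_dir / "sweep.csv", index=False)
    return {"sweeps": summary}


def _run_noisy(config, params, out_dir, seed):
    p = config.params
    noise = stochastic.NoiseConfig(
        tau_xi=p.get("tau_xi", 0.050),
        sigma=tuple(p.get("sigma", (6.0, 6.0, 0.0))),
        dt=p.get("dt", 1e-3),
        T=p.get("T", 1000.0),
        seed=seed,
        mode=p.get("mode", "per-step"),
        burn_in=p.get("burn_in", 5.0),
    )
    I_mean = inputs_for_rates(np.asarray(p["rates"], float), params).I
    res = stochastic.frozen_noise_experiment(
        params, I_mean, noise, p["dI_som"],
        dI_stim=p.get("dI_stim", (1.0, 1.0)),
        stim_amplitude=p.get("stim_amplitude", 1.0),
    )
    return {"noisy": res.summary}


def _run_tuning(config, params, out_dir, seed):
    p = config.params
    exp = tuning.tuning_modulation_experiment(
        params,
        dI_som=p["dI_som"],
        Iback=p.get("Iback", tuning.DEFAULT_BACKGROUND),
        theta_axis=np.asarray(p.get("theta_axis", tuning.DEFAULT_THETA_AXIS)),
        wff=p.get("wff", 2.0),
        theta_p=p.get("theta_p", 90.0),
        sigma_theta=p.get("sigma_theta", 20.0),
    )
    exp.to_frame().to_csv(out_dir / "tuning.csv", index=False)
    decomp = tuning.decompose_experiment(exp)
    return {
        "converged_fraction": float(exp.converged.mean()),
        "decomposition": {
            pop: {
                "slope": d.slope,
                "intercept": d.intercept,
                "intercept_norm": d.intercept_norm,
                "scaling": d.scaling,
                "shift": d.shift,
            }
            for pop, d in decomp.items()
        },
    }


_RUNNERS = {
    "simulate": _run_simulate,
    "scan": _run_scan,
    "vectorfield": _run_vectorfield,
    "sweep": _run_sweep,
    "noisy": _run_noisy,
    "tuning": _run_tuning,
}
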