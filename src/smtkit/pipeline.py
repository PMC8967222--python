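"""Pipeline driver: simulate -> states -> dwell -> report from one config.

Stages run in order; a stage failure halts the run, leaves a ``.failed``
marker next to the partial outputs, and re-raises with the stage name.
Identical config + seed gives identical numeric outputs.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import TrackSet
from .io import RunConfig, dump_json, write_tracks
from .residence import (
    compare_dwell,
    correct_photobleach,
    extract_dwell_times,
    fit_power_law,
    fit_triple_exponential,
    pool_weighted,
)
from .simulate import (
    MotionState,
    SimulationModel,
    simulate_control_dwells,
    simulate_switching_tracks,
)
from .states import filter_states, select_model, state_msd, summarize_fractions

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """What a pipeline run produced, with enough detail to reproduce it."""

    seed: int
    config: dict
    version: str
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "smtkit_version": self.version,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "wall_time_s": self.wall_time_s,
        }


def _model_from_config(spec: dict, seed: int) -> SimulationModel:
    states = tuple(MotionState(**s) for s in spec["states"])
    return SimulationModel(
        states=states,
        initial_weights=tuple(spec["initial_weights"]),
        localization_sigma_um=spec.get("localization_sigma_um", 0.03),
        bleach_rate_s=spec.get("bleach_rate_s", 0.0),
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write all artifacts under ``config.out``."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".failed"
    if marker.exists():
        marker.unlink()
    report = RunReport(seed=config.seed, config=config.raw, version=__version__)
    stage = "setup"
    try:
        protocols = config.protocols
        sim_cfg = config.section("simulate")
        st_cfg = config.section("states")
        dw_cfg = config.section("dwell")

        # -- simulate ---------------------------------------------------
        stage = "simulate"
        tracks: dict[str, TrackSet] = {}
        for channel in ("fast", "slow"):
            if channel not in sim_cfg:
                continue
            spec = sim_cfg[channel]
            if "residence" in spec:
                # bound molecules with power-law residence (residence test bed)
                res = spec["residence"]
                from .simulate import sample_power_law, simulate_bound_tracks

                ts, _truth = simulate_bound_tracks(
                    protocols[channel],
                    n_tracks=spec["n_tracks"],
                    residence_s=lambda rng, n: sample_power_law(
                        rng, n, res["alpha"], res.get("t_min_s", 0.2)
                    ),
                    bleach_amplitudes=res["bleach_amplitudes"],
                    bleach_timescales_s=res["bleach_timescales_s"],
                    d_bound_um2_s=res.get("d_bound_um2_s", 0.005),
                    sigma_um=spec.get("localization_sigma_um", 0.03),
                    n_cells=res.get("n_cells", 1),
                    seed=config.seed,
                )
                _truth.to_csv(out / f"truth_{channel}.csv", index=False)
            else:
                model = _model_from_config(spec, config.seed)
                ts, truth = simulate_switching_tracks(
                    model, protocols[channel], n_tracks=spec["n_tracks"]
                )
                truth.step_labels.to_csv(out / f"truth_{channel}.csv", index=False)
            tracks[channel] = ts
            path = out / f"tracks_{channel}.csv"
            write_tracks(ts, path)
            report.outputs[f"tracks_{channel}"] = {
                "path": str(path),
                "n_tracks": ts.n_tracks,
            }

        # -- diffusive states (fast channel) ----------------------------
        if "fast" in tracks and st_cfg:
            stage = "states"
            model = select_model(
                tracks["fast"],
                K_range=range(st_cfg.get("k_min", 1), st_cfg.get("k_max", 4) + 1),
                n_restarts=st_cfg.get("n_restarts", 5),
                n_perturbations=st_cfg.get("n_perturbations", 10),
                shared_noise=st_cfg.get("shared_noise", False),
                seed=config.seed,
            )
            model = filter_states(
                model,
                min_population=st_cfg.get("min_population", 0.05),
                posterior_threshold=st_cfg.get("posterior_threshold", 0.6),
            )
            frac = summarize_fractions(model, st_cfg.get("bound_D_max_um2_s", 0.03))
            curves = state_msd(model, tracks["fast"], max_lag=st_cfg.get("max_lag", 5))
            dump_json(
                {
                    "K": model.K,
                    "weights": model.weights,
                    "diffusivities_um2_s": model.diffusivities,
                    "epsilon_sq_um2": model.epsilon_sq,
                    "log_likelihood": model.log_likelihood,
                    "bic": model.bic,
                    "bic_table": model.bic_table.to_dict(orient="records")
                    if model.bic_table is not None
                    else None,
                    "converged": bool(model.converged),
                    "n_iter": model.n_iter,
                    "seed": config.seed,
                    "fractions": {
                        "bound": frac.fraction_bound,
                        "confined": frac.fraction_confined,
                        "free": frac.fraction_free,
                        "rule": frac.rule,
                    },
                },
                out / "state_model.json",
            )
            import pandas as pd

            pd.DataFrame(
                {
                    "track_id": np.repeat(model.track_ids, model.K),
                    "state": np.tile(np.arange(model.K), len(model.track_ids)),
                    "posterior": model.posteriors.ravel(),
                }
            ).to_csv(out / "posteriors.csv", index=False)
            pd.concat(
                [
                    pd.DataFrame(
                        {"state": c.state, "lag_s": c.lag_s, "msd_um2": c.msd_um2,
                         "n_effective": c.n_effective}
                    )
                    for c in curves
                ],
                ignore_index=True,
            ).to_csv(out / "msd.csv", index=False)
            report.outputs["state_model"] = {"path": str(out / "state_model.json"), "K": model.K}
            report.warnings.extend(model.warnings)

        # -- residence (slow channel + control) --------------------------
        if "slow" in tracks and "control" in sim_cfg:
            stage = "dwell"
            ctrl_spec = sim_cfg["control"]
            ctrl_model = SimulationModel(
                states=(MotionState("bound", 0.0),),
                initial_weights=(1.0,),
                bleach_mixture=(
                    tuple(ctrl_spec["bleach_amplitudes"]),
                    tuple(ctrl_spec["bleach_timescales_s"]),
                ),
                seed=config.seed,
            )
            control = simulate_control_dwells(
                protocols["slow"], ctrl_model, n_tracks=ctrl_spec["n_tracks"]
            )
            samples = extract_dwell_times(
                tracks["slow"],
                bound_radius_um=dw_cfg.get("bound_radius_um", 0.2),
                min_bound_frames=dw_cfg.get("min_bound_frames", 2),
            )
            pooled = pool_weighted(samples)
            bleach = fit_triple_exponential(pool_weighted([control]), seed=config.seed)
            corrected = correct_photobleach(pooled, bleach)
            pl = fit_power_law(corrected, t_min_s=dw_cfg.get("t_min_s", 0.6))
            stat, p = compare_dwell(pooled, corrected)
            import pandas as pd

            for name, dist in (("raw", pooled), ("corrected", corrected)):
                pd.DataFrame(
                    {"t_s": dist.support_s, "survival": dist.survival}
                ).to_csv(out / f"dwell_survival_{name}.csv", index=False)
            dump_json(
                {
                    "amplitudes": bleach.amplitudes,
                    "timescales_s": bleach.timescales_s,
                    "residual_norm": bleach.residual_norm,
                },
                out / "photobleach_model.json",
            )
            dump_json(
                {
                    "alpha": pl.alpha,
                    "t_min_s": pl.t_min_s,
                    "n_tail": pl.n_tail,
                    "ks_distance": pl.ks_distance,
                    "raw_vs_corrected_ks": {"stat": stat, "p": p},
                },
                out / "power_law.json",
            )
            report.outputs["power_law"] = {"path": str(out / "power_law.json"),
                                           "alpha": pl.alpha}

        stage = "report"
        report.wall_time_s = time.time() - t0
        dump_json(report.to_dict(), out / "run_report.json")
        return report
    except Exception as e:
        marker.write_text(f"stage={stage}\nerror={e}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e
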