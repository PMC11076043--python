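"""Pipeline orchestration: simulate → track → fit from one config.

A run config (dict, or YAML/JSON file via the CLI) lists stages; each
stage's randomness derives from hash(global seed, stage name), so adding
a stage never shifts another stage's draws.  Outputs (CSV/JSON/TIFF) and
a manifest recording inputs, parameters, seeds, and the software version
are written to the output directory; re-running the same config
reproduces identical numeric outputs.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from ._version import __version__
from .density import density_from_particle_counts, lipid_surface_density
from .diffusion import compute_steps, fit_step_distribution, summarize_mobility
from .dwell import compute_dwell_times, fit_survival, mean_dwell, model_mean, select_dwell_model
from .errors import ParameterError
from .kinetics import SensorTrace, kcat_from_trace
from .params import AcquisitionParams, BindingSimConfig, CatalysisSimConfig, ImagingParams
from .synthetic import (
    render_movie,
    simulate_adsorption_trace,
    simulate_catalysis_trace,
    simulate_dwell_sample,
    simulate_track_set,
)
from .tracking import detect_spots, filter_tracks, link_spots
from .tracks import FilterRules, TrackSet


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage_name}".encode()) % (2**31)


def _acq_from(block: dict) -> AcquisitionParams:
    kwargs = dict(block or {})
    if "image_shape" in kwargs and kwargs["image_shape"] is not None:
        kwargs["image_shape"] = tuple(kwargs["image_shape"])
    return AcquisitionParams(**kwargs)


def run_pipeline(config: dict, out_dir, global_seed: Optional[int] = None) -> dict:
    """Execute the configured stages in order and write a manifest.

    Supported stage kinds: ``simulate_dwell``, ``simulate_tracks``,
    ``render_movie``, ``track`` (detect+link+filter), ``dwell_fit``,
    ``diffusion_fit``, ``kinetics_kcat``, ``simulate_catalysis``,
    ``simulate_adsorption``, ``calibrate_density``.  Stages communicate
    through named files in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if global_seed is None else global_seed)
    acq = _acq_from(config.get("acquisition", {}))
    manifest = {"version": __version__, "seed": seed, "stages": [], "outputs": {}}
    state: dict = {}

    try:
        for stage in config.get("stages", []):
            kind = stage["kind"]
            p = dict(stage.get("params", {}))
            s_seed = stage_seed(seed, stage.get("name", kind))
            record = {"kind": kind, "params": p, "seed": s_seed}

            if kind == "simulate_dwell":
                sample = simulate_dwell_sample(
                    n=p["n"],
                    alpha=p.get("alpha", 1.0),
                    tau1_s=p["tau1_s"],
                    tau2_s=p.get("tau2_s"),
                    frame_interval_s=p.get("frame_interval_s", acq.frame_interval_s),
                    min_frames=p.get("min_frames", 2),
                    seed=s_seed,
                )
                path = out / "dwell_sample.csv"
                np.savetxt(path, sample.durations_s, header="dwell_s", comments="")
                state["dwell_sample"] = sample
                manifest["outputs"]["dwell_sample"] = str(path)

            elif kind == "simulate_tracks":
                cfg = BindingSimConfig(**{**p, "seed": s_seed})
                ts = simulate_track_set(cfg, acq)
                path = out / "tracks_simulated.csv"
                ts.to_csv(path)
                state["tracks"] = ts
                manifest["outputs"]["tracks_simulated"] = str(path)

            elif kind == "render_movie":
                imaging = ImagingParams(**{**p, "seed": s_seed})
                stack = render_movie(state["tracks"], acq, imaging)
                path = out / "movie.tif"
                tifffile.imwrite(path, stack)
                state["stack"] = stack
                manifest["outputs"]["movie"] = str(path)

            elif kind == "track":
                stack = state["stack"]
                spots = detect_spots(
                    stack, acq, p.get("sigma_px", 1.2), p["quality_threshold"]
                )
                ts = link_spots(
                    spots, acq, p["max_displacement_um"], p.get("max_gap_frames", 0)
                )
                rules = FilterRules(**p.get("filter", {}))
                ts = filter_tracks(ts, rules)
                path = out / "tracks_detected.csv"
                ts.to_csv(path)
                state["tracks"] = ts
                manifest["outputs"]["tracks_detected"] = str(path)

            elif kind == "dwell_fit":
                sample = state.get("dwell_sample")
                if sample is None:
                    sample = compute_dwell_times(state["tracks"])
                comps = p.get("components", "auto")
                if comps == "auto":
                    fit = select_dwell_model(
                        fit_survival(sample, 1), fit_survival(sample, 2)
                    )
                else:
                    fit = fit_survival(sample, int(comps))
                result = fit.to_dict()
                result["mean_dwell_s"] = mean_dwell(sample)
                result["model_mean_s"] = model_mean(fit)
                path = out / "dwell_fit.json"
                path.write_text(json.dumps(result, indent=2))
                state["dwell_fit"] = fit
                manifest["outputs"]["dwell_fit"] = str(path)

            elif kind == "diffusion_fit":
                steps = compute_steps(state["tracks"])
                fit = fit_step_distribution(
                    steps, p.get("species", 2), p.get("bin_width_um", 0.01)
                )
                result = fit.to_dict()
                result.update(summarize_mobility(steps))
                path = out / "diffusion_fit.json"
                path.write_text(json.dumps(result, indent=2))
                state["diffusion_fit"] = fit
                manifest["outputs"]["diffusion_fit"] = str(path)

            elif kind == "simulate_catalysis":
                cfg = CatalysisSimConfig(**{**p, "seed": s_seed})
                trace = simulate_catalysis_trace(cfg)
                path = out / "catalysis_trace.csv"
                trace.to_csv(path)
                state["trace"] = trace
                manifest["outputs"]["catalysis_trace"] = str(path)

            elif kind == "simulate_adsorption":
                trace = simulate_adsorption_trace(
                    k_obs=p["k_obs"],
                    plateau=p.get("plateau", 1.0),
                    t_grid_s=p["t_grid_s"],
                    noise_sd=p.get("noise_sd", 0.0),
                    seed=s_seed,
                )
                path = out / "adsorption_trace.csv"
                trace.to_csv(path)
                state["trace"] = trace
                manifest["outputs"]["adsorption_trace"] = str(path)

            elif kind == "kinetics_kcat":
                trace = state.get("trace")
                if trace is None:
                    trace = SensorTrace.from_csv(p["trace_csv"])
                res = kcat_from_trace(
                    trace,
                    baseline_window=tuple(p["baseline_window_s"]),
                    plateau_window=tuple(p["plateau_window_s"]),
                    total_density=p["total_density_per_um2"],
                    enzyme_density=p["enzyme_density_per_um2"],
                    depletion_cap=p.get("depletion_cap", 0.1),
                )
                path = out / "kinetics_result.json"
                path.write_text(json.dumps(res.to_dict(), indent=2))
                state["kinetics"] = res
                manifest["outputs"]["kinetics_result"] = str(path)

            elif kind == "calibrate_density":
                if "mole_fraction" in p:
                    d = lipid_surface_density(
                        p["mole_fraction"], p.get("footprint_nm2", 0.72)
                    )
                else:
                    d = density_from_particle_counts(
                        p["n_particles"], p["area_um2"], p["labeled_fraction"]
                    )
                path = out / "density.json"
                path.write_text(
                    json.dumps(
                        {"value_per_um2": d.value_per_um2, "method": d.method}, indent=2
                    )
                )
                manifest["outputs"]["density"] = str(path)

            else:
                raise ParameterError(f"unknown stage kind: {kind}")

            manifest["stages"].append(record)
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
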