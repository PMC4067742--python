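"""End-to-end driver: simulate -> flim-fit -> storm -> morph -> kinetics.

A YAML run configuration declares the seed and one parameter block per
stage; :func:`run_pipeline` executes the requested stages in order and
writes a JSON manifest (inputs, outputs, parameter hash, seed, per-stage
log) sufficient to reproduce a run bit-for-bit for deterministic stages.
All randomness derives from a single seeded generator, so identical
configurations produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import flim, io, kinetics, morphometry, storm, synth

logger = logging.getLogger("flimstorm")

STAGES = ("simulate", "flim_fit", "storm", "morph", "kinetics")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def load_config(path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise PipelineError("config", "not-a-mapping", "config must be a mapping")
    if "seed" in config and not isinstance(config["seed"], int):
        raise PipelineError("config", "bad-seed", "seed must be an integer")
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError("config", "unknown-stage", f"unknown stages {unknown}")


def _param_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir, seed: int = None) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    rng = np.random.default_rng(seed)
    stages = config.get("stages", list(STAGES))
    manifest = {"seed": seed, "param_hash": _param_hash(config),
                "stages": [], "outputs": {}}

    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        params = config.get(stage, {}) or {}
        try:
            log = _STAGE_FUNCS[stage](params, state, rng, out)
        except PipelineError:
            raise
        except Exception as exc:  # surface which stage broke
            raise PipelineError(stage, "stage-failure", str(exc)) from exc
        manifest["stages"].append({"name": stage, "log": log})
        manifest["outputs"].update(log.get("outputs", {}))
        logger.info("stage %s: %s", stage, log)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -- stage implementations --------------------------------------------------

def _stage_simulate(params, state, rng, out):
    log = {"outputs": {}}
    window = params.get("window_ns", synth.DEFAULT_WINDOW_NS)
    n_channels = params.get("n_channels", synth.DEFAULT_N_CHANNELS)
    irf = synth.simulate_irf(params.get("irf_fwhm_ns", 0.2), n_channels, window)
    state["irf"] = irf
    io.write_irf(out / "irf.csv", irf)
    log["outputs"]["irf"] = "irf.csv"

    fl = params.get("flim")
    if fl:
        shape = tuple(fl.get("shape", (16, 16)))
        tau_left = fl.get("tau_left_ns", 3.7)
        tau_right = fl.get("tau_right_ns", 3.3)
        photons = fl.get("photons_per_pixel", 500)
        bgf = fl.get("background_fraction", 0.05)
        truth = [[synth.DecayTruth(tau=tau_left if j < shape[1] // 2 else tau_right,
                                   amplitude_fraction=1 - bgf, n_photons=photons)
                  for j in range(shape[1])] for i in range(shape[0])]
        cube = synth.simulate_tcspc_image(truth, irf, rng)
        state["cube"] = cube
        io.write_decay_cube(out / "tcspc_cube.tif", cube)
        log["outputs"]["tcspc_cube"] = "tcspc_cube.tif"
        log["flim_photons"] = int(cube.counts.sum())

    sm = params.get("storm")
    if sm:
        camera = synth.CameraModel(
            pixel_size=sm.get("pixel_size_nm", 100.0),
            psf_sigma=sm.get("psf_sigma_nm", 150.0),
            background_rate=sm.get("background_rate", 2.0),
            read_noise_sd=sm.get("read_noise_sd", 0.0))
        state["camera"] = camera
        shape = tuple(sm.get("frame_shape", (32, 32)))
        center = (shape[1] * camera.pixel_size / 2,
                  shape[0] * camera.pixel_size / 2)
        emitters = synth.simulate_aggregate_emitters(
            sm.get("kind", "sphere"), sm.get("size_nm", 160.0),
            sm.get("n_fluorophores", 120), center, rng)
        emitters = synth.EmitterSet(
            positions=emitters.positions,
            photons_mean=sm.get("photons_mean", 2000.0),
            on_probability=sm.get("on_probability", 0.005),
            shape_label=emitters.shape_label)
        movie = synth.simulate_blinking_movie(
            emitters, camera, sm.get("n_frames", 400), shape, rng)
        state["movie"] = movie
        io.write_movie(out / "storm_movie.tif", movie)
        log["outputs"]["storm_movie"] = "storm_movie.tif"

    kin = params.get("kinetics")
    if kin:
        times = np.asarray(kin.get("times_hr",
                                   np.linspace(0, 6, 13).tolist()), float)
        trace = synth.simulate_lifetime_timecourse(
            {"L0": kin.get("L0", 3.7), "Linf": kin.get("Linf", 3.3),
             "k": kin.get("k", 2.0), "t50": kin.get("t50", 3.5)},
            times, kin.get("noise_sd", 0.03), rng)
        state["trace"] = trace
        io.write_trace(out / "kinetic_trace.csv", trace)
        log["outputs"]["kinetic_trace"] = "kinetic_trace.csv"
    return log


def _stage_flim_fit(params, state, rng, out):
    cube = state.get("cube")
    irf = state.get("irf")
    if cube is None or irf is None:
        raise PipelineError("flim_fit", "missing-input",
                            "no TCSPC cube available (run simulate first)")
    config = flim.FlimConfig(
        method=params.get("method", "mle"),
        target_min=params.get("target_min", 3500),
        target_max=params.get("target_max", 5000),
        max_factor=params.get("max_factor", 3))
    lt_map = flim.fit_lifetime_map(cube, irf, config=config)
    state["lifetime_map"] = lt_map
    io.write_lifetime_map(out / "lifetime_map.tif", out / "lifetime_map.csv",
                          lt_map)
    summary = flim.region_mean_lifetime([lt_map])
    return {"outputs": {"lifetime_map": "lifetime_map.tif"},
            "binning_factor": lt_map.binning_factor,
            "n_converged": int(lt_map.converged.sum()),
            "mean_tau_ns": summary.mean_tau}


def _stage_storm(params, state, rng, out):
    movie = state.get("movie")
    if movie is None:
        raise PipelineError("storm", "missing-input", "no movie available")
    camera = state.get("camera", synth.CameraModel())
    sp = storm.StormParams(
        pixel_size=camera.pixel_size, psf_sigma=camera.psf_sigma,
        threshold_k=params.get("threshold_k", 6.0),
        window=params.get("window", 7))
    table = storm.localize_stack(movie, sp)
    sr = storm.render_density(table, params.get("bin_nm", 20.0))
    state["loc_table"] = table
    state["sr_image"] = sr
    io.write_localizations(out / "localizations.csv", table)
    io.write_sr_image(out / "sr_image.tif", sr)
    resolution = (storm.estimate_resolution(table, sr) if len(table) else np.nan)
    state["resolution_nm"] = resolution
    return {"outputs": {"localizations": "localizations.csv",
                        "sr_image": "sr_image.tif"},
            "n_localizations": len(table),
            "n_detected": table.n_detected, "n_rejected": table.n_rejected,
            "resolution_nm": resolution}


def _stage_morph(params, state, rng, out):
    sr = state.get("sr_image")
    if sr is None:
        raise PipelineError("morph", "missing-input", "no SR image available")
    records = morphometry.measure_aggregates(
        sr, params.get("min_count", 2), params.get("condition", ""))
    resolution = params.get("resolution_nm", state.get("resolution_nm", 55.0))
    passing = morphometry.filter_by_resolution(records, resolution)
    morphometry.records_frame(records).to_csv(out / "aggregates.csv",
                                              index=False)
    log = {"outputs": {"aggregates": "aggregates.csv"},
           "n_aggregates": len(records), "n_passing": len(passing)}
    if passing:
        summary = morphometry.summarize_sizes(passing)
        log["mean_size_nm"] = summary.mean_size
        log["sem_size_nm"] = summary.sem_size
    return log


def _stage_kinetics(params, state, rng, out):
    trace = state.get("trace")
    if trace is None:
        raise PipelineError("kinetics", "missing-input", "no trace available")
    fit = kinetics.fit_sigmoid(trace)
    result = {"L0": fit.L0, "Linf": fit.Linf, "k_per_hr": fit.k,
              "t50_hr": fit.t50, "lag_hr": fit.lag, "rss": fit.rss}
    (Path(out) / "sigmoid_fit.json").write_text(json.dumps(result, indent=2))
    return {"outputs": {"sigmoid_fit": "sigmoid_fit.json"}, **result}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "flim_fit": _stage_flim_fit,
    "storm": _stage_storm,
    "morph": _stage_morph,
    "kinetics": _stage_kinetics,
}
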