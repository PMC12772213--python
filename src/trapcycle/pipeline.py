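"""Recipe orchestration: chain the analysis stages end to end.

Each recipe mirrors one of the study's workflows:

* ``unloaded``  — simulate/read two-bead traces -> covariance detection ->
  substeps + ensemble averages -> dead-time-truncated dwell MLE;
* ``isometric`` — traces with a clamp force channel -> detection ->
  per-event forces -> Bell MLE;
* ``turnover``  — mantATP single-turnover transient + blank ->
  photobleach subtraction -> single-exponential fit -> SRX/DRX K_EQ;
* ``atpase``    — NADH progress curves -> slopes -> per-head rates ->
  Michaelis-Menten fit;
* ``gliding``   — per-filament velocity table -> weighted Gaussian summary
  -> mixed-motor model fit.

Every stage derives its own RNG substream from the global seed (hashed by
stage name), so adding a stage never perturbs the randomness of earlier
stages; outputs are deterministic given the config and are written as JSON
embedding the resolved config and package version.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import replace
from pathlib import Path
from typing import Callable

import numpy as np

from . import __version__
from .cycle_model import MixtureModel, compute_keq, fit_mixture, summarize_gliding
from .datatypes import EventSet, TrapTrace
from .io import RunConfig, read_gliding, read_trace, read_transient
from .lifetime_stats import fit_exponential_mle
from .synthkin import (
    TransientSimParams,
    TrapSimParams,
    simulate_atpase_progress,
    simulate_gliding_velocities,
    simulate_isometric_trace,
    simulate_transient,
    simulate_unloaded_trace,
)
from .trap_detect import detect_events, fit_cov_double_gaussian, running_covariance
from .trap_mech import annotate_substeps, ensemble_average, event_mean_force, fit_bell
from .transients import correct_photobleach, fit_exp_decay, fit_michaelis_menten, nadh_slope_to_rate

__all__ = ["run_pipeline", "RECIPES", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage substream seed (stable hash of the stage name)."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _detect(trace: TrapTrace, cfg: RunConfig, seed: int) -> EventSet:
    cov = running_covariance(trace, window=cfg.covariance_window)
    thr = fit_cov_double_gaussian(cov, seed=seed)
    return detect_events(cov, thr, dead_time=cfg.dead_time)


def _simulated_traces(cfg: RunConfig, isometric: bool) -> list[tuple[TrapTrace, EventSet]]:
    sim = dict(cfg.simulate)
    n_traces = int(sim.pop("n_traces", 5))
    base = TrapSimParams(**sim)
    out = []
    for i in range(n_traces):
        p = replace(base, seed=stage_seed(cfg.seed, f"simulate/{i}"))
        if isometric:
            out.append(simulate_isometric_trace(p))
        else:
            out.append(simulate_unloaded_trace(p))
    return out


def _load_or_simulate_traces(cfg: RunConfig, isometric: bool):
    paths = cfg.detect.get("trace_paths")
    if paths:
        return [(read_trace(p), None) for p in paths]
    return _simulated_traces(cfg, isometric)


def _recipe_unloaded(cfg: RunConfig) -> dict:
    data = _load_or_simulate_traces(cfg, isometric=False)
    durations, pairs = [], []
    for i, (trace, _) in enumerate(data):
        events = _detect(trace, cfg, stage_seed(cfg.seed, f"detect/{i}"))
        annotate_substeps(trace, events)
        durations.extend(events.durations)
        pairs.extend((trace, ev) for ev in events)
        log.info("trace %d: %d events", i, len(events))
    totals = np.array([ev.total_step for _, ev in pairs])
    totals = totals[np.isfinite(totals)]
    fit = fit_exponential_mle(
        durations, dead_time=cfg.dead_time, n_boot=cfg.bootstrap_n,
        seed=stage_seed(cfg.seed, "lifetimes"),
    )
    result = {
        "n_events": len(pairs),
        "total_step_nm": float(totals.mean()) if totals.size else float("nan"),
        "substep1_nm": float(np.nanmean([ev.substep1 for _, ev in pairs])),
        "substep2_nm": float(np.nanmean([ev.substep2 for _, ev in pairs])),
        "k_detach_per_s": fit.rates[0],
        "k_detach_ci": list(fit.rate_cis[0]),
    }
    if len(pairs) >= 10:
        for direction in ("forward", "reverse"):
            ens = ensemble_average(pairs, direction=direction)
            result[f"ensemble_{direction}_rate_per_s"] = ens.fitted_rate
    return result


def _recipe_isometric(cfg: RunConfig) -> dict:
    data = _load_or_simulate_traces(cfg, isometric=True)
    pairs = []
    for i, (trace, _) in enumerate(data):
        events = _detect(trace, cfg, stage_seed(cfg.seed, f"detect/{i}"))
        for ev in events:
            f = event_mean_force(trace, ev)
            if np.isfinite(f):
                pairs.append((f, ev.duration))
    bell = fit_bell(
        np.array(pairs),
        kT=cfg.kT,
        exclude_above=float(cfg.mech.get("exclude_above", 10.0)),
        dead_time=cfg.dead_time,
        n_boot=cfg.bootstrap_n,
        seed=stage_seed(cfg.seed, "bell"),
    )
    return {
        "n_events": bell.n_events,
        "k0_per_s": bell.k0,
        "k0_ci": list(bell.k0_ci),
        "d_bell_nm": bell.d_bell,
        "d_bell_ci": list(bell.d_ci),
    }


def _recipe_turnover(cfg: RunConfig) -> dict:
    stage = cfg.turnover
    if "sample_path" in stage:
        sample = read_transient(stage["sample_path"])
        blank = read_transient(stage["blank_path"])
    else:
        sim = dict(cfg.simulate)
        sim.setdefault("kind", "mant_turnover")
        sim.setdefault("duration", 1000.0)
        sim.setdefault("n_points", 2000)
        sim.setdefault("bleach_fraction", 0.10)
        params = TransientSimParams(**sim, seed=stage_seed(cfg.seed, "turnover"))
        sample, blank = simulate_transient(params)
    corrected = correct_photobleach(sample, blank)
    fit = fit_exp_decay(corrected, n_phases=1, n_boot=cfg.bootstrap_n,
                        seed=stage_seed(cfg.seed, "turnover-fit"))
    result = {"k_obs_per_s": fit.rates[0], "k_obs_ci": list(fit.rate_cis[0])}
    if "k_drx" in stage:
        t = compute_keq(fit.rates[0], float(stage["k_drx"]))
        result.update({"K_eq": t.K_eq, "frac_drx": t.frac_drx})
    return result


def _recipe_atpase(cfg: RunConfig) -> dict:
    stage = cfg.atpase
    if "curve_paths" in stage:
        curves = [read_transient(p) for p in stage["curve_paths"]]
        concs = list(stage["tf_concs"])
        heads = float(stage["heads_uM"])
    else:
        sim = dict(cfg.simulate)
        concs = sim.pop("tf_concs", [0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 60.0])
        heads = sim.pop("heads", 0.1)
        curves = simulate_atpase_progress(
            vmax=sim.pop("vmax", 2.35), km=sim.pop("km", 7.65),
            tf_concs=concs, heads=heads,
            noise_sd=sim.pop("noise_sd", 0.003),
            seed=stage_seed(cfg.seed, "atpase"), **sim,
        )
    rates = [nadh_slope_to_rate(c, heads=heads) for c in curves]
    mm = fit_michaelis_menten(concs, rates, n_boot=cfg.bootstrap_n,
                              seed=stage_seed(cfg.seed, "atpase-fit"))
    return {
        "vmax_per_s": mm.vmax, "vmax_ci": list(mm.vmax_ci),
        "km_uM": mm.km, "km_ci": list(mm.km_ci),
        "rates_per_s": [float(r) for r in rates],
    }


def _recipe_gliding(cfg: RunConfig) -> dict:
    stage = cfg.gliding
    if "table_path" in stage:
        table = read_gliding(stage["table_path"])
    else:
        sim = dict(cfg.simulate)
        model = MixtureModel(
            v_fast=sim.pop("v_fast", 1.6), v_slow=sim.pop("v_slow", 0.46),
            drag_weight=sim.pop("drag_weight", 8.0),
        )
        table = simulate_gliding_velocities(
            fractions=sim.pop("fractions", [0.0, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0]),
            model=model, seed=stage_seed(cfg.seed, "gliding"), **sim,
        )
    summary = summarize_gliding(table, weighted=bool(stage.get("weighted", True)))
    fitted = fit_mixture(summary[["fraction_slow", "mean_velocity_um_s"]].to_numpy())
    return {
        "summary": summary.to_dict(orient="records"),
        "v_fast_um_s": fitted.v_fast,
        "v_slow_um_s": fitted.v_slow,
        "drag_weight": fitted.drag_weight,
    }


RECIPES: dict[str, Callable[[RunConfig], dict]] = {
    "unloaded": _recipe_unloaded,
    "isometric": _recipe_isometric,
    "turnover": _recipe_turnover,
    "atpase": _recipe_atpase,
    "gliding": _recipe_gliding,
}


def run_pipeline(config: RunConfig, recipe: str) -> dict:
    """Execute one recipe; write ``<recipe>.json`` and a log to output_dir.

    The result JSON embeds the fully resolved config and the package
    version; given the same config and seed the bytes are identical across
    runs.  A stage failure aborts with the stage name and cause.
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / f"{recipe}.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("trapcycle")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("recipe=%s seed=%d", recipe, config.seed)
        try:
            result = RECIPES[recipe](config)
        except Exception as err:
            raise RuntimeError(f"stage failure in recipe {recipe!r}: {err}") from err
        payload = {
            "recipe": recipe,
            "version": __version__,
            "config": config.model_dump(),
            "result": result,
        }
        (outdir / f"{recipe}.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1, allow_nan=True)
        )
        return payload
    finally:
        root.removeHandler(handler)
        handler.close()
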