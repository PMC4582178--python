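"""Configuration-driven pipeline: simulate -> detect -> recurrence / fitdeg.

A pipeline config is a plain mapping (typically loaded from YAML/JSON)
with a global ``seed``, an ``out_dir`` and a ``stages`` mapping.  Only
the stages present are run, in the fixed order simulate, detect,
recurrence, fitdeg; later stages consume the artifacts of earlier ones
unless an explicit input path overrides them.  Every run writes a
manifest with the exact config, package version, stage seeds and SHA-256
hashes of all artifacts, so identical configs produce identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from . import io as cio
from .degreefit import compare_fits
from .recurrence import EmbeddingConfig, surrogate_test
from .synthetic import KernelConfig, ScenarioConfig, generate_degree_sequence, generate_events, render_traces
from .transients import activation_sequence, compute_dff, detect_network_bursts, detect_transients

__all__ = ["run_pipeline", "load_config"]

STAGE_ORDER = ("simulate", "detect", "recurrence", "fitdeg")


def load_config(path: str | Path) -> dict:
    import yaml

    with Path(path).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_stage(cfg: dict, seed: int, out: Path) -> dict:
    kernel_keys = {f.name for f in KernelConfig.__dataclass_fields__.values()}
    kernel_cfg = {k: v for k, v in cfg.items() if k in kernel_keys}
    scen_cfg = {
        k: v for k, v in cfg.items() if k not in kernel_keys and k != "scenario"
    }
    config = ScenarioConfig(
        scenario_name=cfg["scenario"], seed=int(cfg.get("seed", seed)), **{
            k: v for k, v in scen_cfg.items() if k != "seed"
        }
    )
    kernel = KernelConfig(**kernel_cfg)
    events = generate_events(config)
    traces = render_traces(events, kernel, seed=config.seed + 1)
    paths = {
        "traces": cio.write_traces(traces, out / "traces.csv"),
        "events_true": cio.write_event_train(events, out / "events_true.csv"),
    }
    return {"paths": paths, "traces": traces, "seed": config.seed}


def _detect_stage(cfg: dict, state: dict, out: Path) -> dict:
    if "traces" in cfg:
        traces = cio.read_traces(cfg["traces"])
    elif "traces" in state:
        traces = state["traces"]
    else:
        raise ValueError("detect stage: no traces available (run simulate or set 'traces')")
    dff = compute_dff(
        traces,
        baseline_percentile=cfg.get("baseline_percentile", 20.0),
        baseline_window_s=cfg.get("baseline_window_s", 30.0),
    )
    events = detect_transients(
        dff,
        threshold_mads=cfg.get("threshold_mads", 4.0),
        min_rise_s=cfg.get("min_rise_s", 0.6),
        refractory_s=cfg.get("refractory_s", 1.0),
    )
    bursts = detect_network_bursts(
        events,
        sync_window_s=cfg.get("sync_window_s", 1.0),
        min_participation=cfg.get("min_participation", 0.5),
    )
    paths = {
        "events": cio.write_events(events, out / "events.csv"),
        "bursts": cio.write_bursts(bursts, out / "bursts.csv"),
    }
    return {"paths": paths, "events": events, "bursts": bursts}


def _recurrence_stage(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    if "events" in cfg:
        events = cio.read_events(cfg["events"])
    elif "events" in state:
        events = state["events"]
    else:
        raise ValueError(
            "recurrence stage: no events available (run detect or set 'events')"
        )
    seq = activation_sequence(events)
    config = EmbeddingConfig(
        m=cfg.get("m", 5),
        distance_threshold=cfg.get("distance_threshold", 1),
        theiler_window=cfg.get("theiler_window", 0),
        l_min=cfg.get("l_min", 2),
    )
    result = surrogate_test(
        seq,
        config,
        statistic_name=cfg.get("statistic", "determinism_raw"),
        n_surrogates=cfg.get("n_surrogates", 199),
        seed=int(cfg.get("seed", seed)),
    )
    payload = {
        "config": {
            "m": config.m,
            "distance_threshold": config.distance_threshold,
            "theiler_window": config.theiler_window,
            "l_min": config.l_min,
            "statistic": result.statistic_name,
            "n_surrogates": result.n_surrogates,
            "seed": result.seed,
        },
        "sequence_length": len(seq),
        "observed": result.observed,
        "p_value": result.p_value,
    }
    path = cio.write_results(payload, out / "recurrence.json")
    return {"paths": {"recurrence": path}, "recurrence": result}


def _fitdeg_stage(cfg: dict, seed: int, out: Path) -> dict:
    if "histogram" in cfg:
        hist = cio.read_histogram(cfg["histogram"])
    else:
        degrees = generate_degree_sequence(
            cfg.get("model", "hub_mix"),
            cfg.get("params"),
            n_neurons=cfg.get("n_neurons", 69),
            seed=int(cfg.get("seed", seed)),
        )
        cio.write_degree_sequence(degrees, out / "degrees.csv")
        from .degreefit import DegreeHistogram

        hist = DegreeHistogram.from_sequence(degrees)
    comp = compare_fits(
        hist,
        poisson_method=cfg.get("poisson_method", "moment"),
        n_grid_max=cfg.get("n_grid_max", 2000),
        k_min_fit=cfg.get("k_min_fit", 1),
        space=cfg.get("space", "log"),
    )
    payload = {
        "config": {k: v for k, v in cfg.items()},
        "poisson": {"lambda": comp.poisson.lambda_, "sse": comp.poisson.sse,
                    "method": comp.poisson.method},
        "binomial": {"n": comp.binomial.n_param, "P": comp.binomial.p_param,
                     "sse": comp.binomial.sse},
        "powerlaw": {"exponent": comp.powerlaw.exponent_m, "c": comp.powerlaw.c_norm,
                     "k_min_fit": comp.powerlaw.k_min_fit, "sse": comp.powerlaw.sse,
                     "space": comp.powerlaw.space},
        "best_model": comp.best_model,
    }
    path = cio.write_results(payload, out / "degreefit.json")
    return {"paths": {"degreefit": path}, "fit": comp}


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages in order and write artifacts plus a manifest.

    Returns a bundle with the in-memory results, artifact paths and the
    manifest dict.  A stage failure aborts the run with the stage name;
    artifacts of completed stages are left in place.
    """
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")

    state: dict = {}
    artifacts: dict[str, Path] = {}
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        cfg = stages[stage] or {}
        try:
            if stage == "simulate":
                res = _simulate_stage(cfg, seed, out)
                state["traces"] = res["traces"]
            elif stage == "detect":
                res = _detect_stage(cfg, state, out)
                state["events"] = res["events"]
                state["bursts"] = res["bursts"]
            elif stage == "recurrence":
                res = _recurrence_stage(cfg, state, seed, out)
                state["recurrence"] = res["recurrence"]
            else:
                res = _fitdeg_stage(cfg, seed, out)
                state["fit"] = res["fit"]
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        artifacts.update({k: Path(p) for k, p in res["paths"].items()})

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    state["manifest"] = manifest
    state["artifacts"] = artifacts
    state["manifest_path"] = manifest_path
    return state
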