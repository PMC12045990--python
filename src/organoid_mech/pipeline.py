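"""End-to-end orchestration of the four analyses on generated inputs.

``run_pipeline`` reads a JSON configuration, dispatches to the analysis
stages, and writes each stage's tables plus a run manifest sufficient to
reproduce the run (config snapshot, seeds, package version, timestamps).
Stages are pure with respect to their inputs; every output lands in a
named run directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import adc as _adc
from . import network as _network
from . import sholl as _sholl
from . import sls as _sls
from . import synth as _synth
from .errors import ConfigError

__all__ = ["RunManifest", "run_pipeline", "DEMO_CONFIG"]

DEMO_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "rheology": {"n_traces": 6, "noise_frac": 0.02},
        "network": {"p_values": [0.85, 0.95], "seeds": 3, "n_nodes": 64,
                    "n_cells": 32, "R": 10.0},
        "adc": {"n_scans": 3, "snr_b0": 30.0},
        "sholl": {"n_images": 2},
    },
}


@dataclass
class RunManifest:
    """Reproducibility record written alongside every run's outputs."""

    command: str
    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: dict[str, str] = field(default_factory=dict)
    config_sha256: str = ""

    def write(self, out_dir: Path) -> None:
        payload = asdict(self)
        (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2))


def _validate(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config.stages must be a non-empty object")
    known = {"rheology", "network", "adc", "sholl"}
    for key in stages:
        if key not in known:
            raise ConfigError(f"config.stages.{key}: unknown stage (choose from {sorted(known)})")
        if not isinstance(stages[key], dict):
            raise ConfigError(f"config.stages.{key}: must be an object")


def _stage_rheology(params: dict, seed: int, out: Path) -> None:
    traces = _synth.gen_creep_traces(seed=seed,
                                     n_traces=int(params.get("n_traces", 6)),
                                     noise_frac=float(params.get("noise_frac", 0.02)))
    fits = [_sls.fit_sls(_sls.compute_creep_compliance(t)) for t in traces]
    table = _sls.fits_to_frame(fits)
    table.to_csv(out / "fits.csv", index=False)
    pd.DataFrame([{
        "n": len(fits),
        "k0_mean_Pa": table["k0_Pa"].mean(), "k0_sd_Pa": table["k0_Pa"].std(),
        "kst_mean_Pa": table["kst_Pa"].mean(), "kst_sd_Pa": table["kst_Pa"].std(),
        "tau_mean_s": table["tau_s"].mean(), "tau_sd_s": table["tau_s"].std(),
        "r_squared_min": table["r_squared"].min(),
    }]).to_csv(out / "summary.csv", index=False)


def _stage_network(params: dict, seed: int, out: Path) -> None:
    seeds = params.get("seeds", 5)
    if isinstance(seeds, int):
        rng = np.random.default_rng(seed)
        seeds = [int(s) for s in rng.integers(2 ** 31, size=seeds)]
    protocol = _network.CompressionProtocol(
        eval_strain=float(params.get("eval_strain", 0.01)),
        finite_difference_step=float(params.get("fd_step", 1e-3)))
    sweep = _network.stiffness_vs_p_sweep(
        params.get("p_values", [0.85, 0.95]),
        modes=tuple(params.get("modes", ("random", "patterned"))),
        n_nodes=int(params.get("n_nodes", 64)),
        n_cells=int(params.get("n_cells", 32)),
        R=float(params.get("R", 10.0)),
        lam=float(params.get("lam", 1.0)),
        seeds=seeds, protocol=protocol)
    sweep.to_csv(out / "sweep.csv", index=False)
    _network.summarize_sweep(sweep).to_csv(out / "summary.csv", index=False)


def _stage_adc(params: dict, seed: int, out: Path) -> None:
    phantom = _synth.gen_dwi_phantom(seed=seed,
                                     n_scans=int(params.get("n_scans", 5)),
                                     snr_b0=float(params.get("snr_b0", 30.0)))
    keep = int(params.get("keep_modes", _adc.DEFAULT_KEEP_MODES))
    positions: dict[str, dict[str, float]] = {}
    rows = []
    for stack in phantom.stacks:
        seg = _adc.segment_organoids(stack)
        for group in sorted(set(phantom.well_groups)):
            gmask = phantom.group_mask(group) & seg
            amap = _adc.fit_adc_map(stack, mask=gmask)
            pos = _adc.scan_ml_position(amap, keep_modes=keep)
            positions.setdefault(group, {})[stack.scan_id] = pos
            rows.append({"scan_id": stack.scan_id, "group": group,
                         "ml_position_mm2_s": pos})
    pd.DataFrame(rows).to_csv(out / "ml_positions.csv", index=False)
    ref = params.get("reference_group", "control")
    comparison = _adc.group_comparison(positions, reference_group=ref)
    (out / "stats.json").write_text(json.dumps(comparison, indent=2))


def _stage_sholl(params: dict, seed: int, out: Path) -> None:
    n_images = int(params.get("n_images", 2))
    increment = float(params.get("increment", _sholl.DEFAULT_INCREMENT))
    rng = np.random.default_rng(seed)
    profiles = {"ring": [], "scattered": []}
    rows = []
    for mode in profiles:
        for i in range(n_images):
            img = _synth.gen_collagen_image(mode=mode,
                                            seed=int(rng.integers(2 ** 31)),
                                            label=f"{mode}_{i}")
            prof = _sholl.sholl_counts(img, increment=increment)
            profiles[mode].append(prof)
            for r, c in zip(prof.radii, prof.counts):
                rows.append({"label": prof.label, "condition": mode,
                             "radius_norm": r, "count": int(c)})
    pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)
    test = _sholl.compare_profiles(profiles["ring"], profiles["scattered"])
    (out / "stats.json").write_text(json.dumps(
        {"U": test.statistic, "p": test.p_value, "method": test.method,
         "n1": test.n[0], "n2": test.n[1]}, indent=2))


_STAGES: dict[str, Callable[[dict, int, Path], None]] = {
    "rheology": _stage_rheology,
    "network": _stage_network,
    "adc": _stage_adc,
    "sholl": _stage_sholl,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Run the configured stages and write their outputs plus a manifest.

    ``config`` is a dict or a path to a JSON file with a ``stages`` map;
    ``seed`` overrides the config's top-level seed.  Raises
    :class:`~organoid_mech.errors.ConfigError` on schema violations.
    """
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        config = json.loads(path.read_text())
    _validate(config)
    run_seed = int(seed if seed is not None else config.get("seed", 0))

    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command="run_pipeline", config=config, seed=run_seed, version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config_sha256=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest())

    rng = np.random.default_rng(run_seed)
    for name in ("rheology", "network", "adc", "sholl"):
        stage_seed = int(rng.integers(2 ** 31))
        if name not in config["stages"]:
            continue
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        _STAGES[name](config["stages"][name], stage_seed, stage_dir)
        manifest.outputs[name] = str(stage_dir)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out)
    return manifest
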