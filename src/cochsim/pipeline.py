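"""End-to-end orchestration: geometry → arrays → fields → thresholds →
condition experiments, with content-hash caching and structured logging.

Each stage writes its outputs into the run directory and records a hash of
its inputs (config subset + upstream artifact hashes); rerunning with an
unchanged configuration skips completed stages and leaves outputs untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .arrays import fit_centerline, place_contacts
from .cable import PulseSpec, assemble_chain
from .config import RunConfig
from .degeneration import robustness_variants, run_condition
from .fields import solve_field
from .geometry import build_geometry, place_anfs, voxelize
from .population import specificity_map
from .thresholds import threshold_matrix, threshold_search

__all__ = ["run", "summarize", "PipelineError"]

log = logging.getLogger("cochsim.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, path, msg: str):
        super().__init__(f"stage {stage!r} failed on {path}: {msg}")
        self.stage = stage
        self.path = str(path)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Stages:
    """Book-keeping for cached stages in a run directory."""

    def __init__(self, outdir: Path):
        self.path = outdir / ".stage_hashes.json"
        self.hashes = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return self.hashes.get(stage) == key and all(p.exists() for p in outputs)

    def record(self, stage: str, key: str) -> None:
        self.hashes[stage] = key
        self.path.write_text(json.dumps(self.hashes, indent=2))


def _load(stage: str, path: Path, loader):
    try:
        return loader(path)
    except Exception as e:  # corrupted or missing intermediate
        raise PipelineError(stage, path, str(e)) from e


def run(config: RunConfig, outdir) -> Path:
    """Execute the configured pipeline; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2,
                                                   default=str))
    stages = _Stages(outdir)
    cfg_d = config.to_dict()

    def timed(stage, fn):
        t0 = time.time()
        out = fn()
        log.info("stage %s: %.1f s", stage, time.time() - t0)
        return out

    # ---- geometry ---------------------------------------------------------
    key = _hash({"geometry": cfg_d["geometry"], "n": config.n_fibers,
                 "seed": config.seed})
    geo_file = outdir / "geometry.json"
    fib_file = outdir / "fibers.json"
    if not stages.fresh("geometry", key, [geo_file, fib_file]):
        def _geometry():
            geom = build_geometry(config.geometry)
            fibers = place_anfs(geom, n=config.n_fibers, seed=config.seed)
            cio.save_geometry(geom, geo_file)
            cio.save_fibers(fibers, fib_file)
        timed("geometry", _geometry)
        stages.record("geometry", key)
    else:
        log.info("stage geometry: cached")
    geom = _load("geometry", geo_file, cio.load_geometry)
    fibers = _load("geometry", fib_file, cio.load_fibers)
    angles = [f.alpha_deg for f in fibers]

    # ---- arrays -----------------------------------------------------------
    key = _hash({"up": stages.hashes["geometry"], "arrays": config.arrays,
                 "mode": config.orientation_mode})
    array_files = {t: outdir / f"array_{t}.json" for t in config.arrays}
    if not stages.fresh("arrays", key, list(array_files.values())):
        def _arrays():
            for tag in config.arrays:
                cl = fit_centerline(geom, fibers, tag[2:], tag[:2])
                arr = place_contacts(cl, angles,
                                     orientation_mode=config.orientation_mode)
                cio.save_array(arr, array_files[tag])
        timed("arrays", _arrays)
        stages.record("arrays", key)
    else:
        log.info("stage arrays: cached")
    arrays = {t: _load("arrays", p, cio.load_array)
              for t, p in array_files.items()}

    # ---- fields (the expensive stage; cached per contact) -----------------
    key = _hash({"up": stages.hashes["arrays"],
                 "spacing": config.voxel_spacing_um,
                 "rtol": config.solver_rtol})
    field_dir = outdir / "fields"
    field_dir.mkdir(exist_ok=True)
    expected = [field_dir / f"condmap_{t}.npz" for t in config.arrays]
    expected += [field_dir / f"field_{t}_{arrays[t].contacts[i].id}.npz"
                 for t in config.arrays for i in range(len(fibers))]
    if not stages.fresh("fields", key, expected):
        def _fields():
            for tag in config.arrays:
                cmap = voxelize(geom, [arrays[tag]],
                                spacing=config.voxel_spacing_um)
                cio.save_cond_map(cmap, field_dir / f"condmap_{tag}.npz")
                for ct in arrays[tag].contacts:
                    f = field_dir / f"field_{tag}_{ct.id}.npz"
                    if f.exists():
                        continue
                    sol = solve_field(cmap, ct.id, rtol=config.solver_rtol)
                    cio.save_field(sol, f)
        timed("fields", _fields)
        stages.record("fields", key)
    else:
        log.info("stage fields: cached")
    cond_maps = {t: _load("fields", field_dir / f"condmap_{t}.npz",
                          cio.load_cond_map) for t in config.arrays}
    fields = {}
    for tag in config.arrays:
        for ct in arrays[tag].contacts:
            fields[(tag, ct.id)] = _load(
                "fields", field_dir / f"field_{tag}_{ct.id}.npz",
                lambda p, t=tag: cio.load_field(p, cond_maps[t]))

    # ---- threshold experiments -------------------------------------------
    key = _hash({"up": stages.hashes["fields"], "exp": config.experiments,
                 "cond": config.conditions, "pol": config.polarities,
                 "dt": config.dt_ms, "mem": cfg_d["membrane"]})
    done_marker = outdir / "experiments.done.json"
    if not stages.fresh("experiments", key, [done_marker]):
        def _experiments():
            written = []
            for pol in config.polarities:
                baseline = None
                for cond in config.conditions:
                    if ("degeneration" not in config.experiments
                            and cond != "healthy"):
                        continue
                    if "thresholds" not in config.experiments \
                            and "degeneration" not in config.experiments:
                        continue
                    rep = run_condition(fibers, list(arrays.values()), fields,
                                        cond, polarity=pol, baseline=baseline,
                                        dt_ms=config.dt_ms)
                    if cond == "healthy":
                        baseline = rep
                    f = outdir / f"thresholds_{cond}_{pol}.csv"
                    rep.table.to_csv(f, index=False)
                    written.append(f.name)
                if "robustness" in config.experiments:
                    reps = robustness_variants(fibers, list(arrays.values()),
                                               fields, polarity=pol,
                                               dt_ms=config.dt_ms)
                    for name, rep in reps.items():
                        f = outdir / f"robustness_{name}_{pol}.csv"
                        rep.table.to_csv(f, index=False)
                        written.append(f.name)
            if "matrix" in config.experiments or "specificity" in config.experiments:
                for tag in config.arrays:
                    chains = [assemble_chain(f) for f in fibers]
                    by_contact = {ct.id: fields[(tag, ct.id)]
                                  for ct in arrays[tag].contacts}
                    m = threshold_matrix(chains, arrays[tag], by_contact,
                                         "healthy", "cathodic",
                                         dt_ms=config.dt_ms)
                    f = outdir / f"matrix_{tag}_healthy_cathodic.csv"
                    cio.save_matrix(m, f)
                    written.append(f.name)
                    if "specificity" in config.experiments:
                        spec = specificity_map(m)
                        sf = outdir / f"specificity_{tag}.csv"
                        spec.to_frame().to_csv(sf, index_label="fiber")
                        written.append(sf.name)
            done_marker.write_text(json.dumps(sorted(written)))
        timed("experiments", _experiments)
        stages.record("experiments", key)
    else:
        log.info("stage experiments: cached")
    return outdir


def summarize(run_dir) -> dict:
    """Machine-readable medians and orderings for a completed run."""
    run_dir = Path(run_dir)
    cfg_file = run_dir / "config.json"
    if not cfg_file.exists():
        raise PipelineError("summarize", cfg_file, "no completed run found")
    cfg = json.loads(cfg_file.read_text())
    out: dict = {"arrays": cfg["arrays"], "conditions": [], "polarities": [],
                 "median_threshold_ua": {}}
    files = sorted(run_dir.glob("thresholds_*.csv"))
    if not files:
        raise PipelineError("summarize", run_dir, "no threshold tables found")
    for f in files:
        cond, _, pol = f.stem[len("thresholds_"):].rpartition("_")
        if cond not in out["conditions"]:
            out["conditions"].append(cond)
        if pol not in out["polarities"]:
            out["polarities"].append(pol)
        t = pd.read_csv(f)
        for tag, sub in t.groupby("array"):
            med = float(np.nanmedian(sub["threshold_ua"]))
            out["median_threshold_ua"][f"{tag}/{cond}/{pol}"] = med
    (run_dir / "summary.json").write_text(json.dumps(out, indent=2))
    return out
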