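"""Serialization: geometry/fiber/array JSON, conductivity-map and field
containers (NumPy ``.npz`` with a JSON sidecar), threshold CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import Centerline, Contact, ElectrodeArray
from .geometry import (ANFPath, CochlearGeometry, ConductivityMap,
                       GeometryConfig, LABELS)
from .fields import FieldSolution
from .thresholds import ThresholdMatrix

__all__ = [
    "save_geometry", "load_geometry", "save_fibers", "load_fibers",
    "save_array", "load_array", "save_cond_map", "load_cond_map",
    "save_field", "load_field", "save_matrix", "load_matrix",
]


def save_geometry(geom: CochlearGeometry, path) -> None:
    Path(path).write_text(json.dumps(
        {"schema": "cochsim/geometry/v1",
         "config": dataclasses.asdict(geom.config)}, indent=2))


def load_geometry(path) -> CochlearGeometry:
    doc = json.loads(Path(path).read_text())
    cfg = doc["config"]
    for k, v in cfg.items():
        if isinstance(v, list):
            cfg[k] = tuple(v)
    return CochlearGeometry(config=GeometryConfig(**cfg))


def save_fibers(fibers: list[ANFPath], path) -> None:
    Path(path).write_text(json.dumps({
        "schema": "cochsim/fibers/v1",
        "fibers": [
            {"id": f.id, "alpha_deg": f.alpha_deg,
             "dendrite_length": f.dendrite_length,
             "soma_arc_pos": f.soma_arc_pos,
             "points": np.round(f.polyline, 3).tolist()}
            for f in fibers
        ],
    }))


def load_fibers(path) -> list[ANFPath]:
    doc = json.loads(Path(path).read_text())
    return [
        ANFPath(id=d["id"], alpha_deg=d["alpha_deg"],
                polyline=np.asarray(d["points"], dtype=float),
                dendrite_length=d["dendrite_length"],
                soma_arc_pos=d["soma_arc_pos"])
        for d in doc["fibers"]
    ]


def save_array(arr: ElectrodeArray, path) -> None:
    cl = arr.centerline
    Path(path).write_text(json.dumps({
        "schema": "cochsim/array/v1",
        "scala": cl.scala, "style": cl.style,
        "orientation_mode": arr.orientation_mode,
        "alphas": cl.alphas.tolist(),
        "points": np.round(cl.points, 3).tolist(),
        "residuals": cl.residuals,
        "contacts": [
            {"id": c.id, "alpha_deg": c.alpha_deg,
             "center": np.round(c.center, 3).tolist(),
             "orientation": c.orientation.tolist(),
             "radius": c.radius, "height": c.height}
            for c in arr.contacts
        ],
    }))


def load_array(path) -> ElectrodeArray:
    doc = json.loads(Path(path).read_text())
    cl = Centerline(points=np.asarray(doc["points"], dtype=float),
                    alphas=np.asarray(doc["alphas"], dtype=float),
                    scala=doc["scala"], style=doc["style"],
                    residuals=doc.get("residuals", {}))
    contacts = [
        Contact(id=d["id"], alpha_deg=d["alpha_deg"],
                center=np.asarray(d["center"], dtype=float),
                orientation=np.asarray(d["orientation"], dtype=float),
                radius=d["radius"], height=d["height"])
        for d in doc["contacts"]
    ]
    return ElectrodeArray(centerline=cl, contacts=contacts,
                          orientation_mode=doc["orientation_mode"])


def save_cond_map(cmap: ConductivityMap, path) -> None:
    """Binary array container plus JSON sidecar (`<path>.json`)."""
    path = Path(path)
    np.savez_compressed(path, labels=cmap.labels)
    sidecar = {
        "schema": "cochsim/condmap/v1",
        "spacing_um": cmap.spacing,
        "origin_um": np.asarray(cmap.origin, dtype=float).tolist(),
        "shape": list(cmap.shape),
        "label_legend": list(LABELS),
        "sigma_by_label": cmap.sigma_by_label,
        "contact_voxels": {k: v.tolist() for k, v in cmap.contact_voxels.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_cond_map(path) -> ConductivityMap:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cmap = ConductivityMap(
        spacing=side["spacing_um"],
        origin=np.asarray(side["origin_um"], dtype=float),
        labels=data["labels"],
        sigma_by_label=dict(side["sigma_by_label"]),
    )
    cmap.contact_voxels = {k: np.asarray(v, dtype=np.int64)
                           for k, v in side["contact_voxels"].items()}
    cmap.contact_ids = list(cmap.contact_voxels)
    return cmap


def save_field(sol: FieldSolution, path) -> None:
    path = Path(path)
    np.savez_compressed(path, ve_mV=sol.ve)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({
        "schema": "cochsim/field/v1",
        "contact_id": sol.contact_id,
        "injected_current_ua": sol.injected_current_ua,
        "residual": sol.residual,
        "iterations": sol.iterations,
        "spacing_um": sol.cond_map.spacing,
        "origin_um": np.asarray(sol.cond_map.origin, dtype=float).tolist(),
    }))


def load_field(path, cond_map: ConductivityMap) -> FieldSolution:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FieldSolution(ve=data["ve_mV"], cond_map=cond_map,
                         contact_id=side["contact_id"],
                         injected_current_ua=side["injected_current_ua"],
                         residual=side["residual"], iterations=side["iterations"])


def save_matrix(matrix: ThresholdMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label="fiber")
    Path(str(path) + ".json").write_text(json.dumps({
        "schema": "cochsim/threshold-matrix/v1",
        "array": matrix.array_tag, "condition": matrix.condition,
        "polarity": matrix.polarity,
    }))


def load_matrix(path) -> ThresholdMatrix:
    df = pd.read_csv(path, index_col="fiber")
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ThresholdMatrix(values=df.to_numpy(dtype=float),
                           fiber_ids=list(df.index),
                           contact_ids=list(df.columns),
                           array_tag=meta["array"], condition=meta["condition"],
                           polarity=meta["polarity"])
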