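"""File formats: sensor arrays, poses, meshes, data matrices, curves, chains.

User-facing files use millimetres and degrees; the in-memory API is SI
(metres, teslas, radians).  Conversion happens here and only here.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .evidence import PerturbationCurve, ThresholdWidth
from .geometry import RigidTransform, Sensor, SensorArray
from .inversion import DataMatrix
from .search import PoseSample, PosteriorSummary

__all__ = [
    "read_array", "write_array", "read_pose", "write_pose",
    "read_mesh", "write_mesh", "read_data", "write_data",
    "write_leadfield", "read_leadfield",
    "write_curve", "read_curve", "write_chains", "write_posterior",
    "file_hash",
]


def file_hash(path) -> str:
    """SHA-256 of a file, for provenance records."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# -- sensor arrays ----------------------------------------------------------

def write_array(array: SensorArray, path) -> None:
    """JSON (positions in mm) or TSV depending on the file suffix."""
    path = Path(path)
    if path.suffix == ".json":
        doc = {
            "frame": array.frame,
            "sensors": [
                {
                    "label": s.label,
                    "position_mm": (s.position * 1e3).tolist(),
                    "orientation": s.orientation.tolist(),
                    "gain": s.gain,
                }
                for s in array.sensors
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        df = pd.DataFrame({
            "label": array.labels,
            "x_mm": array.positions[:, 0] * 1e3,
            "y_mm": array.positions[:, 1] * 1e3,
            "z_mm": array.positions[:, 2] * 1e3,
            "ox": array.orientations[:, 0],
            "oy": array.orientations[:, 1],
            "oz": array.orientations[:, 2],
            "gain": array.gains,
        })
        df.to_csv(path, sep="\t", index=False)


def read_array(path) -> SensorArray:
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        sensors = tuple(
            Sensor(np.asarray(s["position_mm"], float) * 1e-3,
                   np.asarray(s["orientation"], float),
                   float(s.get("gain", 1.0)), s["label"])
            for s in doc["sensors"])
        return SensorArray(sensors, doc.get("frame", "head"))
    df = pd.read_csv(path, sep="\t")
    sensors = tuple(
        Sensor(np.array([r.x_mm, r.y_mm, r.z_mm]) * 1e-3,
               np.array([r.ox, r.oy, r.oz]), float(r.gain), str(r.label))
        for r in df.itertuples())
    return SensorArray(sensors)


# -- poses ------------------------------------------------------------------

def write_pose(pose: RigidTransform, path) -> None:
    doc = {"rotation_axis_angle_rad": pose.rotvec.tolist(),
           "translation_mm": (pose.translation * 1e3).tolist()}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_pose(path) -> RigidTransform:
    doc = json.loads(Path(path).read_text())
    return RigidTransform(np.asarray(doc["rotation_axis_angle_rad"], float),
                          np.asarray(doc["translation_mm"], float) * 1e-3)


# -- meshes -----------------------------------------------------------------

def read_mesh(path) -> trimesh.Trimesh:
    """OBJ or ASCII-STL surface mesh (vertices in mm, converted to metres)."""
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return trimesh.Trimesh(np.asarray(mesh.vertices) * 1e-3,
                           np.asarray(mesh.faces), process=False)


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    out = trimesh.Trimesh(np.asarray(mesh.vertices) * 1e3,
                          np.asarray(mesh.faces), process=False)
    out.export(str(path))


# -- data matrices ----------------------------------------------------------

def write_data(data: DataMatrix, path) -> None:
    """Channels x samples TSV (label column first) plus a JSON sidecar."""
    path = Path(path)
    labels = list(data.channel_labels) or [
        f"ch{i:03d}" for i in range(data.n_channels)]
    df = pd.DataFrame(data.values, index=pd.Index(labels, name="label"))
    df.to_csv(path, sep="\t")
    sidecar = {"sample_rate_hz": data.sample_rate, "units": "T",
               "n_channels": data.n_channels, "n_samples": data.n_samples}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_data(path) -> DataMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    rate = 1.0
    if sidecar_path.exists():
        rate = float(json.loads(sidecar_path.read_text())["sample_rate_hz"])
    return DataMatrix(df.to_numpy(float), rate, tuple(map(str, df.index)))


# -- lead fields ------------------------------------------------------------

def write_leadfield(leadfield, path, provenance: dict | None = None) -> None:
    """Binary matrix (.npy) with a JSON sidecar describing it."""
    path = Path(path)
    np.save(path, leadfield.matrix)
    doc = {"shape": list(leadfield.matrix.shape),
           "units": "T per (A m)",
           "head_kind": leadfield.head_kind,
           "channel_labels": list(leadfield.channel_labels)}
    if provenance:
        doc["provenance"] = provenance
    path.with_suffix(".json").write_text(json.dumps(doc, indent=1))


def read_leadfield(path):
    from .forward import LeadField

    path = Path(path)
    matrix = np.load(path.with_suffix(".npy"))
    labels = ()
    head_kind = ""
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        labels = tuple(doc.get("channel_labels", ()))
        head_kind = doc.get("head_kind", "")
    return LeadField(matrix, labels, head_kind)


# -- curves, chains, posteriors --------------------------------------------

def write_curve(curve: PerturbationCurve, path,
                width: ThresholdWidth | None = None,
                threshold: float = -3.0) -> None:
    path = Path(path)
    cols = {"offset": curve.offsets, "mean_F": curve.mean_F}
    for r in range(curve.n_repeats):
        cols[f"repeat_{r}"] = curve.F_values[:, r]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    meta = {"kind": curve.kind, "seed": curve.seed,
            "n_repeats": curve.n_repeats, "threshold": threshold}
    if width is not None:
        meta["width"] = {"negative": width.negative,
                         "positive": width.positive,
                         "open_negative": width.open_negative,
                         "open_positive": width.open_positive,
                         "half_width": width.half_width}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


def read_curve(path) -> PerturbationCurve:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    reps = [c for c in df.columns if c.startswith("repeat_")]
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PerturbationCurve(df["offset"].to_numpy(),
                             df[reps].to_numpy(),
                             meta.get("kind", "orientation"),
                             meta.get("seed"))


def write_chains(samples: list[PoseSample], path) -> None:
    rows = [{
        "chain": s.chain_id, "iteration": s.iteration,
        "rx": s.pose.rotvec[0], "ry": s.pose.rotvec[1],
        "rz": s.pose.rotvec[2],
        "tx_mm": s.pose.translation[0] * 1e3,
        "ty_mm": s.pose.translation[1] * 1e3,
        "tz_mm": s.pose.translation[2] * 1e3,
        "F": s.F, "accepted": int(s.accepted),
    } for s in samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_posterior(summary: PosteriorSummary, path, level: float = 0.95
                    ) -> None:
    ell = summary.ellipsoid
    doc = {
        "mean_pose": {
            "rotation_axis_angle_rad": summary.mean_pose.rotvec.tolist(),
            "translation_mm": (summary.mean_pose.translation * 1e3).tolist(),
        },
        "ellipsoid_centre_mm": (ell.centre * 1e3).tolist(),
        "ellipsoid_cov_mm2": (ell.cov * 1e6).tolist(),
        "level": ell.level,
        "volume_cm3": ell.volume_cm3,
        "collapsed": summary.collapsed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))
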