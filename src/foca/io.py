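"""Cohort file formats: tab-delimited tables with provenance headers.

Layout of a cohort directory:

    meta.tsv            one row per subject (id, group, age, sex, mean_fd, ...)
    labels_group.tsv    per-vertex group network labels (1-based)
    labels_<id>.tsv     per-subject truth labels (generator) or individualized
    scan_<id>.tsv       T x V BOLD matrix
    fd_<id>.tsv         per-frame framewise displacement (mm)
    model.json          full generative model (coupling, effects, geometry)

All tables are UTF-8 TSV with a header row; matrices and label maps carry a
single ``#`` comment line with provenance (config hash, seed).  Vertex indices
are 0-based, network ids 1-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .individualize import Parcellation
from .synthgen import (
    EffectSpec,
    LatentCouplingModel,
    Scan,
    SubjectMeta,
    SurfaceGeometry,
)

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_scan",
    "load_scan",
    "save_cohort",
    "load_cohort",
    "save_model",
    "load_model",
    "provenance_hash",
]


def provenance_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def save_matrix(path: str | Path, matrix: np.ndarray, comment: str = "") -> None:
    m = np.atleast_2d(np.asarray(matrix))
    cols = [f"c{j}" for j in range(m.shape[1])]
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(cols) + "\n")
        for row in m:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def load_matrix(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.to_numpy(dtype=float)


def save_scan(directory: str | Path, scan: Scan, comment: str = "") -> None:
    directory = Path(directory)
    sid = scan.meta.subject_id
    save_matrix(directory / f"scan_{sid}.tsv", scan.data, comment)
    save_matrix(directory / f"fd_{sid}.tsv", scan.fd[:, None], comment)
    if scan.true_labels is not None:
        save_matrix(directory / f"labels_{sid}.tsv", scan.true_labels[:, None], comment)


def load_scan(path: str | Path, fd_path: str | Path, meta: SubjectMeta, tr: float = 2.0) -> Scan:
    """Load a T x V TSV scan with its FD sidecar, validating shapes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = load_matrix(path)
    fd = load_matrix(fd_path).ravel()
    if len(fd) != data.shape[0]:
        raise ValueError(
            f"FD length ({len(fd)}) does not match frame count ({data.shape[0]})"
        )
    bad = np.where(~np.isfinite(data).all(axis=1))[0]
    if len(bad):
        raise ValueError(f"NaN/inf frames at indices {bad.tolist()[:20]}")
    return Scan(data=data, tr=tr, fd=fd, censor_mask=np.ones(len(fd), bool), meta=meta)


def _meta_row(m: SubjectMeta) -> dict:
    row = {
        "subject_id": m.subject_id,
        "group": m.group,
        "age": m.age,
        "sex": m.sex,
        "mean_fd": m.mean_fd,
        "scan_birth_interval": m.scan_birth_interval,
    }
    row.update({f"score_{k}": v for k, v in m.behaviour_scores.items()})
    return row


def save_cohort(
    directory: str | Path,
    scans: list[Scan],
    model: LatentCouplingModel | None = None,
    group_labels: np.ndarray | None = None,
    comment: str = "",
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([_meta_row(s.meta) for s in scans]).to_csv(
        directory / "meta.tsv", sep="\t", index=False
    )
    if group_labels is None and model is not None:
        group_labels = model.group_labels
    if group_labels is not None:
        save_matrix(directory / "labels_group.tsv", np.asarray(group_labels)[:, None], comment)
    for scan in scans:
        save_scan(directory, scan, comment)
    if model is not None:
        save_model(directory / "model.json", model)


def load_cohort(directory: str | Path, tr: float = 2.0):
    """Load scans, metadata and (if present) group labels and model."""
    directory = Path(directory)
    meta_df = pd.read_csv(directory / "meta.tsv", sep="\t")
    scans = []
    for _, row in meta_df.iterrows():
        scores = {
            c[len("score_"):]: float(row[c])
            for c in meta_df.columns
            if c.startswith("score_") and np.isfinite(row[c])
        }
        meta = SubjectMeta(
            subject_id=str(row["subject_id"]),
            group=str(row.get("group", "adult")),
            age=float(row.get("age", 30.0)),
            sex=str(row.get("sex", "F")),
            mean_fd=float(row.get("mean_fd", 0.0)),
            scan_birth_interval=float(row.get("scan_birth_interval", 0.0)),
            behaviour_scores=scores,
        )
        sid = meta.subject_id
        scan = load_scan(
            directory / f"scan_{sid}.tsv", directory / f"fd_{sid}.tsv", meta, tr=tr
        )
        lbl = directory / f"labels_{sid}.tsv"
        if lbl.exists():
            scan.true_labels = load_matrix(lbl).ravel().astype(int)
        scans.append(scan)
    group_labels = None
    gl = directory / "labels_group.tsv"
    if gl.exists():
        group_labels = load_matrix(gl).ravel().astype(int)
    model = None
    mj = directory / "model.json"
    if mj.exists():
        model = load_model(mj)
    return scans, group_labels, model


def save_model(path: str | Path, model: LatentCouplingModel) -> None:
    eff = model.effects
    payload = {
        "k_networks": model.k_networks,
        "coupling": model.coupling.tolist(),
        "group_labels": model.group_labels.tolist(),
        "geometry": {
            "vertex_coords": model.geometry.vertex_coords.tolist(),
            "edges": model.geometry.edges.tolist(),
            "hemisphere": model.geometry.hemisphere.tolist(),
        },
        "effects": {
            "boundary_shift_rate": eff.boundary_shift_rate,
            "global_weight": eff.global_weight,
            "noise_sd": eff.noise_sd,
            "age_effects": {f"{i},{j}": s for (i, j), s in eff.age_effects.items()},
            "age_reference": eff.age_reference,
            "behaviour_weights": {
                name: {
                    "network": int(sp["network"]),
                    "weights": list(map(float, sp["weights"])),
                    "noise_sd": float(sp.get("noise_sd", 0.0)),
                }
                for name, sp in eff.behaviour_weights.items()
            },
        },
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> LatentCouplingModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    geo = payload["geometry"]
    geometry = SurfaceGeometry(
        vertex_coords=np.asarray(geo["vertex_coords"], dtype=float),
        edges=np.asarray(geo["edges"], dtype=int),
        hemisphere=np.asarray(geo["hemisphere"]),
    )
    eff = payload["effects"]
    effects = EffectSpec(
        boundary_shift_rate=eff["boundary_shift_rate"],
        global_weight=eff["global_weight"],
        noise_sd=eff["noise_sd"],
        age_effects={
            tuple(int(x) for x in key.split(",")): slope
            for key, slope in eff["age_effects"].items()
        },
        age_reference=eff.get("age_reference", 40.5),
        behaviour_weights=eff.get("behaviour_weights", {}),
    )
    return LatentCouplingModel(
        k_networks=payload["k_networks"],
        coupling=np.asarray(payload["coupling"], dtype=float),
        group_labels=np.asarray(payload["group_labels"], dtype=int),
        geometry=geometry,
        effects=effects,
    )


def group_parcellation_from_labels(labels: np.ndarray, k: int | None = None) -> Parcellation:
    labels = np.asarray(labels, dtype=int)
    if k is None:
        k = int(labels.max())
    return Parcellation(labels=labels, n_networks=k, level="group")
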