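"""Readers and writers for the package's interchange formats.

Meshes go to PLY (binary little-endian) or OBJ with vertex units in
micrometres; segmented spines are written as numbered PLY files plus a JSON
index; feature tables, CLDH rows and expert label tables are CSV.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import trimesh
import yaml

from .cldh import CLDH
from .segmentation import SpineMesh


def save_mesh(path, mesh: trimesh.Trimesh):
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in (".ply", ".obj"):
        raise ValueError("mesh export supports .ply and .obj")
    mesh.export(str(path))


def load_mesh(path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh")
    return m


def save_spines(out_dir, spines, prefix="spine"):
    """Write spines as numbered PLYs plus ``index.json`` (id, vertex/face
    counts, base centroid, patch face indices)."""
    os.makedirs(out_dir, exist_ok=True)
    index = []
    for i, s in enumerate(spines):
        name = f"{prefix}_{i:03d}.ply"
        s.mesh.export(os.path.join(out_dir, name))
        index.append({
            "spine_id": i,
            "file": name,
            "n_vertices": int(len(s.mesh.vertices)),
            "n_faces": int(len(s.mesh.faces)),
            "base_centroid": [float(v) for v in s.base_centroid],
            "patch_faces": [int(f) for f in s.patch_faces],
        })
    with open(os.path.join(out_dir, "index.json"), "w") as fh:
        json.dump(index, fh, indent=1)
    return index


def load_spines(out_dir) -> list:
    with open(os.path.join(out_dir, "index.json")) as fh:
        index = json.load(fh)
    spines = []
    for rec in index:
        mesh = trimesh.load(os.path.join(out_dir, rec["file"]), force="mesh")
        spines.append(SpineMesh(
            mesh=mesh,
            patch_faces=np.asarray(rec["patch_faces"], dtype=int),
            base_centroid=np.asarray(rec["base_centroid"], dtype=float),
        ))
    return spines


def save_feature_table(path, table: pd.DataFrame):
    with open(path, "w") as fh:
        fh.write("# units: L,AD um; V,CHV um^3; S,FA um^2; OA rad; "
                 "CHR,CVD unitless; LVR um^-2; LAR um^-1\n")
        table.to_csv(fh)


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def save_cldh_table(path, histograms, ids=None):
    """One CSV row per spine: 100 bins + n_chords + max_length + seed."""
    rows = []
    for h in histograms:
        row = {f"cldh_{i:03d}": b for i, b in enumerate(h.bins)}
        row.update(n_chords=h.n_chords, max_length=h.max_length,
                   seed=h.seed if h.seed is not None else "")
        rows.append(row)
    idx = ids if ids is not None else range(len(rows))
    pd.DataFrame(rows, index=pd.Index(idx, name="spine_id")).to_csv(path)


def load_cldh_table(path):
    df = pd.read_csv(path, index_col=0)
    bins_cols = [c for c in df.columns if c.startswith("cldh_")]
    out = []
    for _, row in df.iterrows():
        seed = row.get("seed")
        out.append(CLDH(
            bins=row[bins_cols].to_numpy(dtype=float),
            n_chords=int(row["n_chords"]),
            max_length=float(row["max_length"]),
            seed=None if pd.isna(seed) or seed == "" else int(seed),
        ))
    return out, df.index


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
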