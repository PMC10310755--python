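"""Classic morphometric features of a segmented spine mesh.

All distance-based features are measured from the base centroid ``c`` (the
area-weighted centroid of the patch closing the spine's cut base) to the
true surface vertices of the spine.  Fan-apex vertices introduced by the
patching are excluded from the vertex sets; boundary-loop vertices are kept,
since they lie on the real surface.

Features (units):
    L    spine length (um): mean |p_i - c| over the 5% of surface vertices
         farthest from c
    V    volume (um^3), S surface area (um^2), CHV convex hull volume (um^3)
    CHR  convex hull ratio (CHV - V) / V, dimensionless
    AD   mean |p_j - c| over all surface vertices (um)
    CVD  coefficient of variation of those distances (population SD / mean)
    OA   open angle (rad): mean angle between p_i - c and the mean direction
    FA   foot area (um^2): total area of the base patch(es)
    LVR  L / V (um^-2), LAR  L / S (um^-1)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .meshing import convex_hull_volume, mesh_area, mesh_volume
from .segmentation import SpineMesh

FEATURE_COLUMNS = ["L", "V", "S", "CHV", "CHR", "AD", "CVD", "OA", "FA", "LVR", "LAR"]


@dataclass(frozen=True)
class ClassicFeatures:
    L: float
    V: float
    S: float
    CHV: float
    CHR: float
    AD: float
    CVD: float
    OA: float
    FA: float
    LVR: float
    LAR: float

    def as_dict(self):
        return asdict(self)


def _surface_distances(spine: SpineMesh):
    ids = spine.surface_vertex_indices
    pts = np.asarray(spine.mesh.vertices, dtype=float)[ids]
    return np.linalg.norm(pts - spine.base_centroid[None, :], axis=1), pts


def spine_length(spine: SpineMesh) -> float:
    """Mean distance from the base centroid over the top-5% farthest
    surface vertices (n = max(1, ceil(0.05 N)))."""
    d, _ = _surface_distances(spine)
    n_all = len(d)
    if n_all < 20:
        raise ValueError(f"too few surface vertices ({n_all} < 20)")
    n = max(1, math.ceil(0.05 * n_all))
    top = np.sort(d)[-n:]
    return float(top.mean())


def distance_stats(spine: SpineMesh):
    """(AD, CVD): mean and coefficient of variation (population SD / mean)
    of base-centroid distances over all surface vertices."""
    d, _ = _surface_distances(spine)
    if len(d) < 4:
        raise ValueError("need at least 4 surface vertices")
    mean = float(d.mean())
    if mean <= 1e-12:
        raise ValueError("degenerate spine: zero mean distance")
    return mean, float(d.std() / mean)


def open_angle(spine: SpineMesh) -> float:
    """Mean unsigned angle between each vertex direction ``p_i - c`` and
    the mean of those directions.  Undefined (raises) when the mean
    direction vanishes, e.g. a full sphere centred on ``c``."""
    _, pts = _surface_distances(spine)
    dirs = pts - spine.base_centroid[None, :]
    mean_dir = dirs.mean(axis=0)
    nm = np.linalg.norm(mean_dir)
    if nm < 1e-9:
        raise ValueError("undefined open angle: mean direction vanishes")
    lens = np.linalg.norm(dirs, axis=1)
    ok = lens > 1e-12
    cosang = np.clip((dirs[ok] @ mean_dir) / (lens[ok] * nm), -1.0, 1.0)
    return float(np.arccos(cosang).mean())


def convex_hull_ratio(spine: SpineMesh) -> float:
    """(CHV - V) / V; zero for convex spines, grows with concavity
    (e.g. the waist under a mushroom head)."""
    v = mesh_volume(spine.mesh)
    if v <= 0:
        raise ValueError("zero spine volume")
    chv = convex_hull_volume(spine.mesh)
    return float((chv - v) / v)


def foot_area(spine: SpineMesh) -> float:
    """Total area of the base patch triangles (all patched loops)."""
    if spine.patch_faces.size == 0:
        raise ValueError("spine has no base patch")
    tri = np.asarray(spine.mesh.triangles, dtype=float)[spine.patch_faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return float(areas.sum())


def extract_classic_features(spine: SpineMesh) -> ClassicFeatures:
    """Assemble all 11 classic features for one spine.

    A degenerate open angle (radially symmetric spine) is recorded as NaN
    with a warning rather than failing the whole spine.
    """
    L = spine_length(spine)
    V = mesh_volume(spine.mesh)
    S = mesh_area(spine.mesh)
    CHV = convex_hull_volume(spine.mesh)
    CHR = (CHV - V) / V
    AD, CVD = distance_stats(spine)
    try:
        OA = open_angle(spine)
    except ValueError:
        warnings.warn("open angle undefined for this spine; recording NaN",
                      stacklevel=2)
        OA = float("nan")
    FA = foot_area(spine)
    return ClassicFeatures(
        L=L, V=V, S=S, CHV=CHV, CHR=CHR, AD=AD, CVD=CVD, OA=OA, FA=FA,
        LVR=L / V, LAR=L / S,
    )


def feature_table(spines, ids=None) -> pd.DataFrame:
    """Feature DataFrame: one row per spine, 11 named columns."""
    if ids is None:
        ids = list(range(len(spines)))
    rows = [extract_classic_features(s).as_dict() for s in spines]
    return pd.DataFrame(rows, index=pd.Index(ids, name="spine_id"))[FEATURE_COLUMNS]
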