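"""Chord length distribution histogram (CLDH).

The CLDH summarizes a 3D shape by the distribution of lengths of chords —
straight segments whose endpoints lie on the surface and whose interior lies
inside the object.  Chords are sampled by a Monte-Carlo procedure: two
points are drawn uniformly w.r.t. area on the mesh surface, a ray is cast
from outside the mesh through both points, and the sorted ray/mesh
intersections are paired consecutively into interior segments whose lengths
are recorded.  Normalizing each object's lengths by their maximum before
binning makes the 100-bin histogram invariant to translation, rotation and
scale.  Histograms are compared with the Jensen-Shannon distance (base-2
logs, so values lie in [0, 1]).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.special import rel_entr


@dataclass(frozen=True)
class CLDH:
    """Normalized chord-length histogram.

    Attributes
    ----------
    bins : ndarray (n_bins,)
        Probabilities over the normalized length range [0, 1]; sum to 1.
    n_chords : int
        Number of chords binned.
    max_length : float
        Normalization constant (longest observed chord, um) so the absolute
        scale is recoverable.
    seed : int or None
        RNG seed used when sampling, for provenance.
    """

    bins: np.ndarray
    n_chords: int
    max_length: float
    seed: object = None

    def __post_init__(self):
        bins = np.asarray(self.bins, dtype=float)
        object.__setattr__(self, "bins", bins)
        if bins.ndim != 1 or len(bins) < 1:
            raise ValueError("bins must be a 1D vector")
        if np.any(bins < 0) or abs(bins.sum() - 1.0) > 1e-9:
            raise ValueError("bins must be non-negative and sum to 1")
        if self.n_chords <= 0:
            raise ValueError("n_chords must be positive")
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")


def sample_surface_pair(mesh: trimesh.Trimesh, rng: np.random.Generator):
    """Two distinct points uniform w.r.t. surface area.

    Triangles are chosen area-weighted; positions are uniform barycentric.
    """
    pts = _sample_surface(mesh, 2, rng)
    while np.linalg.norm(pts[0] - pts[1]) < 1e-12:
        pts[1] = _sample_surface(mesh, 1, rng)[0]
    return pts[0], pts[1]


def _sample_surface(mesh: trimesh.Trimesh, n, rng: np.random.Generator):
    tri = np.asarray(mesh.triangles, dtype=float)
    areas = np.asarray(mesh.area_faces, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero-area mesh")
    fi = rng.choice(len(tri), size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a, b, c = tri[fi, 0], tri[fi, 1], tri[fi, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def _ray_mesh_ts(origins, dirs, tri, chunk=256):
    """Moller-Trumbore line parameters t for ray batches against all
    triangles.  Returns a list of 1D arrays of t values (t >= 0)."""
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    out = []
    for s in range(0, len(origins), chunk):
        o = origins[s : s + chunk]
        d = dirs[s : s + chunk]
        p = np.cross(d[:, None, :], e2[None, :, :])           # (r, f, 3)
        det = np.einsum("fj,rfj->rf", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o[:, None, :] - v0[None, :, :]
        u = np.einsum("rfj,rfj->rf", tvec, p) * inv
        q = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rfj,rj->rf", q, d) * inv
        t = np.einsum("fj,rfj->rf", e2, q) * inv
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t >= 0)
        for r in range(len(o)):
            out.append(t[r][hit[r]])
    return out


def cast_chords(
    mesh: trimesh.Trimesh,
    n_chords: int,
    rng: np.random.Generator,
    batch: int = 2048,
    max_discard_frac: float = 0.5,
):
    """Sample at least ``n_chords`` chord lengths by surface-pair ray casting.

    For each sampled surface pair a ray is cast from one bounding-box
    diagonal before the first point, through both points; sorted
    intersections are deduplicated (tolerance 1e-9 x bbox diagonal) and
    paired consecutively (1-2, 3-4, ...) into interior segments.  Rays with
    an odd intersection count are discarded and counted; a discard fraction
    above ``max_discard_frac`` signals a broken mesh and raises.
    """
    if n_chords < 1:
        raise ValueError("n_chords must be >= 1")
    if not mesh.is_watertight:
        raise ValueError("cast_chords requires a watertight mesh")
    if mesh.volume == 0:
        raise ValueError("mesh encloses no interior")
    tri = np.asarray(mesh.triangles, dtype=float)
    diag = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    tol = 1e-9 * diag

    lengths = []
    n_rays = 0
    n_discard = 0
    while len(lengths) < n_chords:
        p = _sample_surface(mesh, 2 * batch, rng).reshape(batch, 2, 3)
        d = p[:, 1] - p[:, 0]
        dn = np.linalg.norm(d, axis=1)
        good = dn > 1e-12
        p, d, dn = p[good], d[good], dn[good]
        d = d / dn[:, None]
        origins = p[:, 0] - d * diag
        ts_list = _ray_mesh_ts(origins, d, tri)
        for ts in ts_list:
            n_rays += 1
            ts = np.sort(ts)
            if len(ts) > 1:
                keep = np.ones(len(ts), dtype=bool)
                keep[1:] = np.diff(ts) > tol
                ts = ts[keep]
            if len(ts) < 2 or len(ts) % 2 == 1:
                n_discard += 1
                continue
            segs = ts[1::2] - ts[0::2]
            lengths.extend(segs[segs > tol].tolist())
        if n_rays >= 64 and n_discard > max_discard_frac * n_rays:
            raise RuntimeError(
                f"{n_discard}/{n_rays} rays discarded (odd intersection "
                "counts): mesh is likely broken"
            )
    if n_discard:
        warnings.warn(
            f"discarded {n_discard}/{n_rays} rays with odd intersection counts",
            stacklevel=2,
        )
    return np.asarray(lengths)


def build_cldh(lengths, n_bins: int = 100, normalize: bool = True, seed=None) -> CLDH:
    """Bin chord lengths into an ``n_bins`` histogram summing to 1.

    With ``normalize=True`` lengths are divided by their maximum first, so
    bins cover [0, 1] and the maximum falls in the last bin.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty chord length list")
    if np.any(lengths <= 0):
        raise ValueError("chord lengths must be positive")
    max_length = float(lengths.max())
    vals = lengths / max_length if normalize else lengths
    hi = 1.0 if normalize else max_length
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, hi))
    bins = counts / counts.sum()
    return CLDH(bins=bins, n_chords=len(lengths), max_length=max_length, seed=seed)


def compute_cldh(
    mesh: trimesh.Trimesh, n_chords: int = 30_000, n_bins: int = 100, seed=0
) -> CLDH:
    """Convenience: cast chords and build the histogram in one call.

    30,000 chords is the default at which replicate histograms of the same
    spine stop being distinguishable (their Jensen-Shannon distance
    plateaus)."""
    rng = np.random.default_rng(seed)
    lengths = cast_chords(mesh, n_chords, rng)
    return build_cldh(lengths, n_bins=n_bins, seed=seed)


def _as_bins(h):
    if isinstance(h, CLDH):
        return h.bins
    return np.asarray(h, dtype=float)


def jensen_shannon_distance(P, Q) -> float:
    """Jensen-Shannon distance between two histograms.

    ``sqrt(0.5 KL(P||M) + 0.5 KL(Q||M))`` with ``M = (P+Q)/2`` and base-2
    logarithms, so the value lies in [0, 1]; zero-probability terms
    contribute 0.
    """
    p, q = _as_bins(P), _as_bins(Q)
    if p.shape != q.shape:
        raise ValueError("histograms must have equal bin counts")
    for name, h in (("P", p), ("Q", q)):
        if np.any(h < 0) or abs(h.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a normalized histogram")
    m = 0.5 * (p + q)
    # rel_entr uses natural logs; convert to base 2.
    div = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    div /= np.log(2.0)
    return float(np.sqrt(max(div, 0.0)))


def pairwise_distance_matrix(histograms) -> np.ndarray:
    """Symmetric matrix of Jensen-Shannon distances between histograms."""
    hs = [_as_bins(h) for h in histograms]
    n = len(hs)
    if n < 2:
        raise ValueError("need at least 2 histograms")
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = jensen_shannon_distance(hs[i], hs[j])
    return out


def convergence_curve(
    spine_mesh: trimesh.Trimesh, n_grid, reps: int = 2, rng=None, n_bins: int = 100
):
    """Mean JSD between independently re-sampled replicate CLDHs per chord
    count — diagnoses how many chords the histogram needs to stabilize.

    Returns (n_grid, mean_jsd array).
    """
    n_grid = list(n_grid)
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])) or not n_grid:
        raise ValueError("n_grid must be non-empty and strictly ascending")
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    if rng is None:
        rng = np.random.default_rng()
    means = []
    for n in n_grid:
        seeds = rng.integers(0, 2**31 - 1, size=reps)
        if len(set(seeds.tolist())) < reps:
            raise ValueError("identical replicate seeds: invalid comparison")
        hs = []
        for s in seeds:
            sub = np.random.default_rng(int(s))
            hs.append(build_cldh(cast_chords(spine_mesh, int(n), sub), n_bins=n_bins))
        ds = [
            jensen_shannon_distance(hs[i], hs[j])
            for i, j in itertools.combinations(range(reps), 2)
        ]
        means.append(float(np.mean(ds)))
    return np.asarray(n_grid), np.asarray(means)
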