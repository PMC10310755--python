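"""Mesh skeletonization and spine/shaft segmentation.

Pipeline: a curve skeleton of the dendrite mesh is extracted; the skeleton is
reduced by collapsing degree-2 chains; among the longest leaf-to-leaf paths
of the reduced graph the straightest one (minimum sum of turning angles) is
taken as the dendrite shaft, on the assumption that the shaft is relatively
linear while spines branch off at an angle.  Surface vertices mapped to
non-shaft skeleton nodes are labeled spine directly; vertices mapped to the
shaft are relabeled spine when their distance to the shaft polyline exceeds
the SENSITIVITY-quantile of that distance distribution (this rescues small
spines whose surface contracts onto the shaft skeleton).  Spine-labeled
connected components are finally cut out and closed with fan-triangulated
base patches.

The skeletonizer is contract-level: the solid enclosed by the mesh is
voxelized and thinned to a one-voxel-wide curve skeleton, a graph is built
over 26-connected skeleton voxels, and every mesh vertex is mapped to its
nearest skeleton node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import morphology


@dataclass
class SkeletonGraph:
    """Curve skeleton: node positions, connectivity, mesh-vertex map.

    Attributes
    ----------
    positions : ndarray (n_nodes, 3)
        Node coordinates in micrometres (same frame as the mesh).
    graph : networkx.Graph
        Nodes are integer ids ``0..n_nodes-1``.
    vertex_map : ndarray (n_mesh_vertices,)
        For every mesh vertex, the id of the skeleton node it maps to.
    """

    positions: np.ndarray
    graph: nx.Graph
    vertex_map: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.vertex_map = np.asarray(self.vertex_map, dtype=int)
        n = len(self.positions)
        if n == 0:
            raise ValueError("empty skeleton")
        if self.graph.number_of_nodes() != n:
            raise ValueError("graph nodes must match positions")
        if n > 1 and not nx.is_connected(self.graph):
            raise ValueError("skeleton graph must be connected")
        if self.vertex_map.size and (
            self.vertex_map.min() < 0 or self.vertex_map.max() >= n
        ):
            raise ValueError("vertex_map refers to unknown skeleton nodes")


@dataclass
class ReducedGraph:
    """Skeleton with degree-2 nodes collapsed into annotated chains.

    ``graph`` nodes are the retained (degree != 2) skeleton node ids; each
    edge ``(u, v)`` carries attribute ``chain``: the ordered list of interior
    skeleton node ids it replaced, oriented from ``u`` to ``v``.
    """

    graph: nx.Graph
    positions: np.ndarray

    def expand_edge(self, u, v):
        """Full node sequence u..v including interior chain nodes (the
        stored chain orientation is recorded in the edge's ``u`` attribute
        and reversed here when traversed the other way)."""
        data = self.graph.get_edge_data(u, v)
        chain = list(data["chain"])
        if data["u"] != u:
            chain.reverse()
        return [u] + chain + [v]

    def leaves(self):
        return [n for n in self.graph.nodes if self.graph.degree(n) <= 1]


@dataclass
class VertexLabels:
    """Per-mesh-vertex spine/shaft labels (``is_spine`` boolean array)."""

    is_spine: np.ndarray

    def __post_init__(self):
        self.is_spine = np.asarray(self.is_spine, dtype=bool)


@dataclass
class SpineMesh:
    """A closed spine mesh with its base patch.

    Attributes
    ----------
    mesh : trimesh.Trimesh
        Watertight mesh of the spine after base patching.
    patch_faces : ndarray
        Face indices of all base-patch (fan) triangles.
    base_centroid : ndarray (3,)
        Area-weighted centroid of the largest patch; reference point ``c``
        for distance-based features.
    """

    mesh: trimesh.Trimesh
    patch_faces: np.ndarray
    base_centroid: np.ndarray
    analytic: dict = field(default_factory=dict)  # generator ground truth, if any

    def __post_init__(self):
        self.patch_faces = np.asarray(self.patch_faces, dtype=int)
        self.base_centroid = np.asarray(self.base_centroid, dtype=float)
        if self.patch_faces.size == 0:
            raise ValueError("patch_faces must be non-empty")

    @property
    def surface_vertex_indices(self) -> np.ndarray:
        """Vertices of the true spine surface: referenced by at least one
        non-patch face.  Boundary-loop vertices are included; fan apex
        vertices (patch-only) are excluded."""
        mask = np.ones(len(self.mesh.faces), dtype=bool)
        mask[self.patch_faces] = False
        return np.unique(self.mesh.faces[mask])


def skeletonize(mesh: trimesh.Trimesh, pitch=None) -> SkeletonGraph:
    """Extract a curve skeleton of the solid enclosed by a watertight mesh.

    The mesh is voxelized at ``pitch`` (default: max bbox extent / 100),
    filled, and thinned with 3D morphological skeletonization; the skeleton
    voxels become graph nodes connected by 26-neighbourhood adjacency.  Every
    mesh vertex maps to its nearest skeleton node.
    """
    if not mesh.is_watertight:
        raise ValueError("skeletonize requires a watertight mesh")
    extent = mesh.bounding_box.primitive.extents
    if pitch is None:
        pitch = float(np.max(extent)) / 100.0
    pitch = float(pitch)
    if pitch <= 0:
        raise ValueError("pitch must be positive")

    vg = mesh.voxelized(pitch)
    filled = vg.copy().fill()
    matrix = np.asarray(filled.matrix, dtype=bool)
    skel = morphology.skeletonize(matrix)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        # Thinning collapsed the object entirely; fall back to its centroid.
        coords = np.argwhere(matrix)
        coords = coords[[len(coords) // 2]]
    positions = filled.indices_to_points(coords)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(coords)))
    tree = cKDTree(coords.astype(float))
    for i, j in tree.query_pairs(r=np.sqrt(3.0) + 1e-6):
        graph.add_edge(int(i), int(j))

    # Voxel thinning leaves lattice-scale zigzag in node positions, which
    # would corrupt turning-angle sums along paths; relax interior (degree-2)
    # nodes toward their neighbour mean to recover a smooth centerline.
    positions = _smooth_chain_positions(graph, positions)

    if len(positions) > 1 and not nx.is_connected(graph):
        comps = sorted(nx.connected_components(graph), key=len, reverse=True)
        warnings.warn(
            f"skeleton split into {len(comps)} components; keeping the largest",
            stacklevel=2,
        )
        keep = sorted(comps[0])
        remap = {old: new for new, old in enumerate(keep)}
        graph = nx.relabel_nodes(graph.subgraph(keep).copy(), remap)
        positions = positions[keep]

    vtree = cKDTree(positions)
    _, vertex_map = vtree.query(np.asarray(mesh.vertices, dtype=float), workers=-1)
    return SkeletonGraph(positions=positions, graph=graph, vertex_map=vertex_map)


def _smooth_chain_positions(graph: nx.Graph, positions, iterations=15, lam=0.5):
    """Laplacian smoothing of degree-2 node positions (leaves and junctions
    stay pinned)."""
    pos = np.asarray(positions, dtype=float).copy()
    deg2 = [n for n in graph.nodes if graph.degree(n) == 2]
    if not deg2:
        return pos
    nbrs = {n: list(graph.neighbors(n)) for n in deg2}
    idx = np.asarray(deg2, dtype=int)
    for _ in range(iterations):
        means = np.stack([pos[nbrs[n]].mean(axis=0) for n in deg2])
        pos[idx] = (1 - lam) * pos[idx] + lam * means
    return pos


def _break_cycles(g: nx.Graph) -> nx.Graph:
    """Break every cycle by removing the middle edge of its longest
    degree-2 chain segment, keeping all nodes."""
    g = g.copy()
    while True:
        basis = nx.cycle_basis(g)
        if not basis:
            return g
        cycle = basis[0]
        n = len(cycle)
        deg = dict(g.degree())
        # Split the cycle into runs between anchor (degree != 2) nodes; if
        # the cycle is pure degree-2, the whole ring is one chain.
        anchors = [i for i, node in enumerate(cycle) if deg[node] != 2]
        if not anchors:
            edge = (cycle[0], cycle[1])
        else:
            best_len, best_edge = -1, None
            for k, ai in enumerate(anchors):
                aj = anchors[(k + 1) % len(anchors)]
                run = (aj - ai) % n or n
                if run > best_len:
                    mid = (ai + run // 2) % n
                    best_len = run
                    best_edge = (cycle[mid], cycle[(mid + 1) % n])
            edge = best_edge
        warnings.warn("skeleton contains a cycle; breaking it", stacklevel=3)
        g.remove_edge(*edge)


def reduce_graph(g: SkeletonGraph) -> ReducedGraph:
    """Collapse degree-2 chains of the skeleton into annotated edges.

    The result is acyclic: cycles in the input are broken first (with a
    warning) by removing one edge in the longest chain of each cycle, so the
    expanded chains still cover every original node.
    """
    if g.graph.number_of_nodes() == 0:
        raise ValueError("empty skeleton graph")
    work = _break_cycles(g.graph)

    deg = dict(work.degree())
    anchors = {n for n, d in deg.items() if d != 2}
    if not anchors:
        # Single pure path cannot occur (its endpoints have degree 1); an
        # isolated node has degree 0 and is an anchor. Defensive fallback:
        anchors = {min(work.nodes)}

    reduced = nx.Graph()
    reduced.add_nodes_from(anchors)
    visited_edges = set()
    for a in anchors:
        for nb in work.neighbors(a):
            if (a, nb) in visited_edges:
                continue
            chain = []
            prev, cur = a, nb
            while cur not in anchors:
                chain.append(cur)
                nxts = [x for x in work.neighbors(cur) if x != prev]
                prev, cur = cur, nxts[0]
            visited_edges.add((a, nb))
            visited_edges.add((cur, prev))
            if reduced.has_edge(a, cur):
                continue  # cannot happen after cycle breaking, kept defensive
            reduced.add_edge(a, cur, chain=chain, u=a)
    return ReducedGraph(graph=reduced, positions=g.positions)


def sum_path_angle(positions) -> float:
    """Sum of unsigned turning angles along an ordered 3D polyline.

    At each interior node the angle between the incoming and outgoing
    segment directions (in [0, pi]) is accumulated; a 2-node path has
    angle 0.  A straight shaft scores near 0; kinked paths score high.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 path nodes")
    seg = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    if np.any(lens < 1e-12):
        raise ValueError("repeated consecutive positions in path")
    d = seg / lens[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    return float(np.arccos(cosang).sum())


def _expand_path(rg: ReducedGraph, anchor_path) -> list:
    nodes = [anchor_path[0]]
    for u, v in zip(anchor_path[:-1], anchor_path[1:]):
        nodes.extend(rg.expand_edge(u, v)[1:])
    return nodes


def select_shaft(rg: ReducedGraph, g: SkeletonGraph, m: int = 5) -> set:
    """Pick the skeleton node set of the dendrite shaft.

    All leaf-to-leaf simple paths of the reduced graph are expanded back to
    full skeleton node sequences and ranked by node count; among the ``m``
    longest, the one with the minimum sum of turning angles wins (the shaft
    is assumed near-linear while spine branches turn sharply).  Assumes a
    single dendrite shaft in the scene.
    """
    leaves = rg.leaves()
    if rg.graph.number_of_nodes() == 1:
        only = next(iter(rg.graph.nodes))
        if rg.graph.number_of_edges() == 0:
            raise ValueError("cannot select a shaft from a single skeleton node")
        leaves = [only]
    if len(leaves) < 2:
        raise ValueError("need at least two skeleton leaves to select a shaft")

    candidates = []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            anchor_path = nx.shortest_path(rg.graph, leaves[i], leaves[j])
            expanded = _expand_path(rg, anchor_path)
            candidates.append((anchor_path, expanded))
    candidates.sort(key=lambda c: len(c[1]), reverse=True)
    candidates = candidates[: max(1, int(m))]

    # The turning-angle sum is taken over the reduced path's anchor nodes
    # (leaves and junctions): junction-to-junction legs are straight by
    # construction, so the comparison measures genuine bends (a branch
    # turning off into a spine) rather than lattice-scale wiggle of the
    # voxel chains, which would grow with path length and drown the signal.
    def angle_of(cand):
        anchor_path, _ = cand
        pts = g.positions[anchor_path]
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
        if len(pts) < 3:
            return 0.0
        return sum_path_angle(pts)

    best = min(candidates, key=angle_of)
    anchor_path, expanded = best

    # When the skeleton end retracts into a spine near the field border,
    # the longest path terminates at that spine's tip.  A genuine shaft leg
    # continues the path direction; a spine leg turns away sharply.  Trim
    # terminal legs that bend more than ~60 degrees at their junction.
    anchor_path = list(anchor_path)
    max_bend = np.deg2rad(60.0)
    for _ in range(2):
        trimmed = False
        if len(anchor_path) >= 3:
            for end in (0, -1):
                a, b, c = (
                    (anchor_path[0], anchor_path[1], anchor_path[2])
                    if end == 0
                    else (anchor_path[-1], anchor_path[-2], anchor_path[-3])
                )
                leg = g.positions[b] - g.positions[a]
                main = g.positions[c] - g.positions[b]
                nl, nm = np.linalg.norm(leg), np.linalg.norm(main)
                if nl < 1e-12 or nm < 1e-12:
                    continue
                bend = np.arccos(np.clip(np.dot(leg, main) / (nl * nm), -1, 1))
                if bend > max_bend:
                    anchor_path = (
                        anchor_path[1:] if end == 0 else anchor_path[:-1]
                    )
                    trimmed = True
                    break
        if not trimmed:
            break
    expanded = _expand_path(rg, anchor_path)
    expanded = _trim_bent_ends(expanded, g.positions, max_bend)
    return set(int(n) for n in expanded)


def _trim_bent_ends(path, positions, max_bend, stride=3, frac=0.35):
    """Cut a sharp bend near either end of an expanded path.

    A spine without its own junction (its attachment junction disappears
    when the adjacent shaft stub retracts during thinning) shows up as a
    sharp bend inside the terminal chain itself; scan windowed directions
    over the first/last ``frac`` of the path and cut at the first bend
    exceeding ``max_bend``.
    """
    path = list(path)
    for _ in range(2):  # once per end
        n = len(path)
        if n < 3 * stride:
            break
        pts = positions[path]
        limit = max(2, int(frac * n) // stride)
        dirs = []
        for j in range(limit + 1):
            a, b = j * stride, min((j + 1) * stride, n - 1)
            if a >= b:
                break
            v = pts[b] - pts[a]
            nv = np.linalg.norm(v)
            if nv < 1e-12:
                continue
            dirs.append((b, v / nv))
        # Compare against the terminal direction: a smooth skeleton smears
        # a sharp junction turn over several windows, so consecutive-window
        # bends stay small even where the total turn is ~90 degrees.
        cut = None
        if dirs:
            u0 = dirs[0][1]
            for b1, w in dirs[1:]:
                if np.arccos(np.clip(np.dot(u0, w), -1, 1)) > max_bend:
                    cut = b1
                    break
        if cut is not None and cut < n - 3:
            path = path[cut:]
        path.reverse()  # handle the other end on the next sweep
    return path


def _point_segment_distances(points, seg_a, seg_b):
    """Min distance from each point to any segment (vectorized, O(n*m))."""
    ab = seg_b - seg_a  # (m, 3)
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.maximum(ab2, 1e-18)
    # (n, m, 3) broadcasting in chunks to bound memory
    n = len(points)
    out = np.full(n, np.inf)
    chunk = max(1, int(4e6 // max(1, len(seg_a))))
    for s in range(0, n, chunk):
        p = points[s : s + chunk]
        ap = p[:, None, :] - seg_a[None, :, :]
        tpar = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
        proj = seg_a[None, :, :] + tpar[:, :, None] * ab[None, :, :]
        d = np.linalg.norm(p[:, None, :] - proj, axis=2)
        out[s : s + chunk] = d.min(axis=1)
    return out


def label_surface_vertices(
    mesh: trimesh.Trimesh,
    g: SkeletonGraph,
    shaft: set,
    sensitivity: float,
    smooth_iters: int = 2,
) -> VertexLabels:
    """Label every mesh vertex shaft or spine.

    Vertices mapped to non-shaft skeleton nodes are spine.  Vertices mapped
    to shaft nodes get their distance to the nearest point of the shaft
    polyline (segments, not nodes, so node spacing does not quantize the
    threshold); those strictly above the ``sensitivity``-quantile of that
    distance distribution are relabeled spine.  ``sensitivity = 1`` relabels
    nothing, ``sensitivity = 0`` relabels everything above the minimum.
    """
    if not shaft:
        raise ValueError("empty shaft node set")
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must be in [0, 1]")
    shaft = set(int(n) for n in shaft)
    unknown = shaft - set(g.graph.nodes)
    if unknown:
        raise ValueError(f"shaft contains unknown skeleton nodes: {sorted(unknown)[:5]}")

    shaft_mask_per_node = np.zeros(len(g.positions), dtype=bool)
    shaft_mask_per_node[list(shaft)] = True
    verts = np.asarray(mesh.vertices, dtype=float)

    seg_a, seg_b = [], []
    sub = g.graph.subgraph(shaft)
    for u, v in sub.edges:
        seg_a.append(g.positions[u])
        seg_b.append(g.positions[v])
    if seg_a:
        seg_a = np.asarray(seg_a)
        seg_b = np.asarray(seg_b)
        d0 = _point_segment_distances(
            verts[shaft_mask_per_node[g.vertex_map]], seg_a, seg_b
        )
        # Thinning retracts the skeleton from the shaft's ends by about one
        # radius; extrapolate the polyline beyond its endpoints so vertices
        # near the ends are measured against the axis, not the retracted tip.
        bounds = np.asarray(mesh.bounds, dtype=float)
        ext = float(np.linalg.norm(bounds[1] - bounds[0]))
        for e in [n for n in sub.nodes if sub.degree(n) == 1]:
            # Extend along a principal-axis fit of the terminal run of
            # nodes.  The last few nodes themselves are excluded from the
            # fit and the ray is anchored on the fitted line: thinning
            # wanders off-axis near flat cut faces, and a ray through the
            # wandering tip misses the shaft's cross-section.
            run = [e]
            prev = None
            cur = e
            for _ in range(35):
                nxt = [x for x in sub.neighbors(cur) if x != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                run.append(cur)
            pts_run = g.positions[run]
            if len(run) < 2:
                continue
            fit_pts = pts_run[5:] if len(pts_run) >= 12 else pts_run
            centroid = fit_pts.mean(axis=0)
            _, _, vt = np.linalg.svd(fit_pts - centroid, full_matrices=False)
            direction = vt[0]
            if np.dot(direction, g.positions[e] - centroid) < 0:
                direction = -direction
            reach = float(np.dot(g.positions[e] - centroid, direction))
            anchor = centroid + max(reach, 0.0) * direction
            seg_a = np.vstack([seg_a, anchor])
            seg_b = np.vstack([seg_b, anchor + direction * ext])

        # Branch (non-shaft) skeleton nodes that still lie inside the shaft
        # tube do not represent protruding geometry: spine branches start at
        # the shaft axis, and surface vertices all around the junction —
        # including the far side of the shaft — contract onto them.  Treat
        # nodes within the estimated shaft radius as shaft-like.
        r_est = float(np.median(d0)) if len(d0) else np.inf
        node_dist = _point_segment_distances(g.positions, seg_a, seg_b)
        shaft_like = shaft_mask_per_node | (node_dist <= 1.3 * r_est)
        mapped_shaft = shaft_like[g.vertex_map]
        is_spine = ~mapped_shaft
        idx = np.flatnonzero(mapped_shaft)
        d = _point_segment_distances(verts[idx], seg_a, seg_b)
    else:  # single-node shaft: distance to the node
        mapped_shaft = shaft_mask_per_node[g.vertex_map]
        is_spine = ~mapped_shaft
        idx = np.flatnonzero(mapped_shaft)
        node = next(iter(shaft))
        d = np.linalg.norm(verts[idx] - g.positions[node], axis=1)
    if len(idx):
        thresh = float(np.quantile(d, sensitivity))
        is_spine[idx[d > thresh]] = True

    # Majority-vote smoothing over mesh neighbourhoods removes speckle
    # labels and thin label gaps that would shatter one spine into several
    # components.
    if smooth_iters > 0:
        n = len(is_spine)
        edges = mesh.edges_unique
        import scipy.sparse as sp

        adj = sp.coo_matrix(
            (np.ones(2 * len(edges)),
             (np.concatenate([edges[:, 0], edges[:, 1]]),
              np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        deg[deg == 0] = 1
        lab = is_spine.astype(float)
        for _ in range(smooth_iters):
            frac = adj.dot(lab) / deg
            lab = (frac > 0.5).astype(float)
        is_spine = lab.astype(bool)
    return VertexLabels(is_spine=is_spine)


def _boundary_loops(faces_kept, vertex_count):
    """Ordered boundary loops of a face subset, oriented as in the faces."""
    edge_count = {}
    directed = {}
    for f in faces_kept:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
            directed[(a, b)] = True
    boundary = [
        (a, b)
        for (a, b) in directed
        if edge_count[(min(a, b), max(a, b))] == 1
    ]
    # Walk directed boundary edges into closed loops.  The walk is
    # edge-based so boundaries that touch themselves at a vertex (bowtie
    # configurations) still decompose into valid loops.
    out_edges = {}
    for a, b in boundary:
        out_edges.setdefault(a, []).append(b)
    unused = set(boundary)
    loops = []
    for e0 in boundary:
        if e0 not in unused:
            continue
        a0, b0 = e0
        unused.discard(e0)
        loop = [a0]
        cur = b0
        ok = True
        while cur != a0:
            loop.append(cur)
            nxt = None
            for cand in out_edges.get(cur, ()):
                if (cur, cand) in unused:
                    nxt = cand
                    break
            if nxt is None:
                ok = False
                break
            unused.discard((cur, nxt))
            cur = nxt
        if ok:
            # A figure-eight walk revisits a vertex; split it into simple
            # loops so the fan patch never duplicates a spoke edge.
            loops.extend(_split_simple_loops(loop))
    return loops


def _split_simple_loops(loop):
    out = []
    path = []
    where = {}
    for v in loop:
        if v in where:
            i = where[v]
            cyc = path[i:]
            if len(cyc) >= 3:
                out.append(cyc)
            for u in cyc:
                where.pop(u, None)
            del path[i:]
        where[v] = len(path)
        path.append(v)
    if len(path) >= 3:
        out.append(path)
    return out


def extract_spines(
    mesh: trimesh.Trimesh,
    labels: VertexLabels,
    min_vertices: int = 20,
    min_volume: float = 0.0,
) -> list:
    """Cut spine-labeled connected components into closed SpineMesh objects.

    A face survives only if all three of its vertices belong to the spine
    component; each resulting boundary loop is closed by a triangle fan from
    the loop centroid.  The base centroid is the area-weighted centroid of
    the largest-area patch.  Components with fewer than ``min_vertices``
    vertices are dropped (binarization noise suppression).
    """
    is_spine = labels.is_spine
    if len(is_spine) != len(mesh.vertices):
        raise ValueError("labels must cover every mesh vertex")
    if not is_spine.any():
        return []

    vgraph = nx.Graph()
    spine_ids = np.flatnonzero(is_spine)
    vgraph.add_nodes_from(spine_ids.tolist())
    edges = mesh.edges_unique
    both = is_spine[edges[:, 0]] & is_spine[edges[:, 1]]
    vgraph.add_edges_from(edges[both].tolist())

    faces = np.asarray(mesh.faces)
    verts = np.asarray(mesh.vertices, dtype=float)
    spines = []
    for comp in nx.connected_components(vgraph):
        if len(comp) < min_vertices:
            continue
        comp_mask = np.zeros(len(verts), dtype=bool)
        comp_mask[list(comp)] = True
        fmask = comp_mask[faces].all(axis=1)
        kept = faces[fmask]
        if len(kept) == 0:
            continue
        sub_ids = np.unique(kept)
        remap = -np.ones(len(verts), dtype=int)
        remap[sub_ids] = np.arange(len(sub_ids))
        new_faces = remap[kept]
        new_verts = verts[sub_ids].tolist()

        loops = _boundary_loops(new_faces.tolist(), len(sub_ids))
        if not loops:
            continue  # closed blob with no connection to the shaft: skip
        patch_faces = []
        patch_info = []  # (area, centroid, face index range)
        all_faces = new_faces.tolist()
        for loop in loops:
            centroid = np.mean([new_verts[i] for i in loop], axis=0)
            ci = len(new_verts)
            new_verts.append(centroid.tolist())
            start = len(all_faces)
            for a, b in zip(loop, loop[1:] + loop[:1]):
                all_faces.append([a, b, ci])
            idxs = list(range(start, len(all_faces)))
            patch_faces.extend(idxs)
            tri = np.asarray(
                [[new_verts[f[0]], new_verts[f[1]], new_verts[f[2]]]
                 for f in all_faces[start:]],
                dtype=float,
            )
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            centroids = tri.mean(axis=1)
            total = areas.sum()
            c = (
                (centroids * areas[:, None]).sum(axis=0) / total
                if total > 0
                else centroid
            )
            patch_info.append((total, c, idxs))

        smesh = trimesh.Trimesh(
            vertices=np.asarray(new_verts), faces=np.asarray(all_faces), process=False
        )
        smesh.remove_unreferenced_vertices()
        trimesh.repair.fix_normals(smesh)
        if not smesh.is_watertight:
            trimesh.repair.fill_holes(smesh)
            trimesh.repair.fix_normals(smesh)
        if not smesh.is_watertight:
            warnings.warn("extracted spine is not watertight; skipping", stacklevel=2)
            continue
        if smesh.volume < 0:
            smesh.invert()
        if smesh.volume < min_volume:
            continue
        largest = max(patch_info, key=lambda t: t[0])
        spines.append(
            SpineMesh(
                mesh=smesh,
                patch_faces=np.asarray(patch_faces, dtype=int),
                base_centroid=largest[1],
            )
        )
    return spines
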