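"""End-to-end segmentation pipeline: stack -> binarize -> reconstruct ->
skeletonize -> shaft selection -> vertex labels -> spine meshes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import imaging, meshing, segmentation


def _drop_border_spines(spines, mesh, margin):
    """Exclude spines touching the field-of-view border (standard
    practice: structures cut by the crop cannot be measured).  The border
    here is the long (x) axis of the dendrite crop."""
    if margin <= 0 or not spines:
        return spines
    lo = float(np.min(mesh.vertices[:, 2]))
    hi = float(np.max(mesh.vertices[:, 2]))
    kept = []
    for s in spines:
        x = s.mesh.vertices[:, 2]
        if x.min() > lo + margin and x.max() < hi - margin:
            kept.append(s)
    return kept


@dataclass
class SegmentationOutput:
    volume: object
    mesh: object
    skeleton: object
    reduced: object
    shaft: set
    labels: object
    spines: list


def segment_stack(
    img: imaging.VoxelImage,
    base_thres: float,
    blend: float = 0.5,
    window=(5, 15, 15),
    sensitivity: float = 0.85,
    min_vertices: int = 20,
    recon_voxel_size=None,
    recon_depth: int = 8,
    skeleton_pitch=None,
    n_longest_paths: int = 5,
    border_margin: float = 0.25,
    min_volume: float = 0.05,
) -> SegmentationOutput:
    """Run the full spine-segmentation pipeline on one confocal stack.

    ``recon_voxel_size`` defaults to twice the lateral voxel size laterally
    and the axial step axially — fine enough to preserve necks, coarse
    enough to keep downstream graph work fast.
    """
    vol = imaging.binarize(img, base_thres=base_thres, t=blend, window=window)
    vol = imaging.largest_component(vol)
    samples = imaging.extract_surface_samples(vol)
    if recon_voxel_size is None:
        dz, dy, dx = img.spacing
        recon_voxel_size = (max(dz, 2 * dy), 2 * dy, 2 * dx)
    mesh = meshing.reconstruct_surface(
        samples, depth=recon_depth, voxel_size=recon_voxel_size
    )
    skel = segmentation.skeletonize(mesh, pitch=skeleton_pitch)
    reduced = segmentation.reduce_graph(skel)
    shaft = segmentation.select_shaft(reduced, skel, m=n_longest_paths)
    labels = segmentation.label_surface_vertices(mesh, skel, shaft, sensitivity)
    spines = segmentation.extract_spines(
        mesh, labels, min_vertices=min_vertices, min_volume=min_volume
    )
    spines = _drop_border_spines(spines, mesh, margin=border_margin)
    return SegmentationOutput(
        volume=vol, mesh=mesh, skeleton=skel, reduced=reduced, shaft=shaft,
        labels=labels, spines=spines,
    )
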