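"""Volume, surface-vertex and curvature-spot morphometry of 3D cell masks.

A cell is represented as a binary voxel occupancy grid; its surface is the
0.5-level isosurface triangulation (marching cubes).  Membrane protrusions
are detected as connected surface patches of unusually high discrete mean
curvature: per-vertex curvature is estimated from a ball-neighborhood
measure, vertices above a cohort quantile are flagged, flagged vertices are
clustered along mesh edges, and clusters whose surface area exceeds a
minimum patch area count as protrusions.

The vertex/curvature pipeline of commercial "surface mode" tools is
proprietary, so absolute vertex counts from this module are comparable only
within this module's own parameters — relative contrasts (more/fewer
vertices, larger/smaller volume) are the meaningful outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from skimage import measure


@dataclass
class CellMask:
    """Binary voxel occupancy of one cell at one frame."""

    occupancy: np.ndarray                       # 3D bool
    voxel_size: tuple[float, float, float]      # μm
    cell_id: str = "C1"
    t: float = 0.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        self.occupancy = occ.astype(bool)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def validate(self) -> None:
        """Raise if the mask is empty or has several foreground components."""
        if not self.occupancy.any():
            raise ValueError(f"mask {self.cell_id!r}: empty foreground")
        _, n = ndimage.label(self.occupancy)
        if n != 1:
            raise ValueError(
                f"mask {self.cell_id!r}: {n} connected components, expected 1")


@dataclass
class SurfaceMesh:
    """Triangulated cell surface with optional per-vertex mean curvature."""

    vertices: np.ndarray                 # (n, 3) μm
    faces: np.ndarray                    # (m, 3) int
    mean_curvature: np.ndarray | None = dc_field(default=None)  # 1/μm

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def euler_characteristic(self) -> int:
        return self.to_trimesh().euler_number

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)

    @property
    def enclosed_volume(self) -> float:
        """Volume by the divergence theorem on the triangulation (μm³)."""
        return float(abs(self.to_trimesh().volume))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_volume(mask: CellMask) -> float:
    """Cell volume: foreground voxel count × voxel volume (μm³)."""
    mask.validate()
    return float(mask.occupancy.sum()) * mask.voxel_volume


def extract_surface(mask: CellMask) -> SurfaceMesh:
    """0.5-level isosurface of the binary grid, vertex coordinates in μm.

    The grid is zero-padded so the mesh is always closed and lightly
    Gaussian-smoothed (σ = 1 voxel) before contouring to remove the
    staircase artifact of a binary isosurface, which otherwise inflates
    surface area; coincident vertices are welded.
    """
    mask.validate()
    padded = np.pad(mask.occupancy, 2).astype(np.float32)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    if smoothed.max() <= 0.5:   # mask too small to survive smoothing
        smoothed = padded
    padded = smoothed
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=mask.voxel_size)
    verts -= 2.0 * np.asarray(mask.voxel_size)  # undo the pad offset
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if tm.volume < 0:       # orient faces so normals point outward
        tm.invert()
    if not tm.is_watertight:
        raise ValueError(f"mask {mask.cell_id!r}: extracted surface is not "
                         "watertight")
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       faces=np.asarray(tm.faces))


def count_vertices(mesh: SurfaceMesh) -> int:
    """Number of distinct (welded) surface vertices — the protrusiveness
    proxy used alongside volume."""
    return mesh.n_vertices


def vertex_mean_curvature(mesh: SurfaceMesh,
                          smooth_iters: int = 5) -> np.ndarray:
    """Per-vertex discrete mean curvature (1/μm), outward-convex positive.

    Cotangent-Laplacian estimator: the mean-curvature normal at vertex i is
    K_i = Σ_j (cot α_ij + cot β_ij)(x_j − x_i) / (2 A_i) with A_i the
    barycentric one-ring area, and H_i = ±|K_i|/2 signed by comparison with
    the outward vertex normal.  ``smooth_iters`` rounds of one-ring umbrella
    averaging suppress residual voxelization noise.
    """
    tm = mesh.to_trimesh()
    V = np.asarray(tm.vertices)
    F = np.asarray(tm.faces)
    n = len(V)
    lap = np.zeros_like(V)
    area = np.zeros(n)
    for c in range(3):
        i = F[:, c]
        j = F[:, (c + 1) % 3]
        k = F[:, (c + 2) % 3]
        # cotangent of the angle at k, opposite edge (i, j)
        u = V[i] - V[k]
        v = V[j] - V[k]
        cross = np.cross(u, v)
        cn = np.linalg.norm(cross, axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cn, 1e-12)
        np.add.at(lap, i, cot[:, None] * (V[j] - V[i]))
        np.add.at(lap, j, cot[:, None] * (V[i] - V[j]))
        np.add.at(area, i, cn / 6.0)   # face area / 3, once per corner
    K = lap / (2.0 * np.maximum(area, 1e-12)[:, None])
    h = 0.5 * np.linalg.norm(K, axis=1)
    # K points opposite the outward normal on a convex surface
    sign = -np.sign(np.einsum("ij,ij->i", K, np.asarray(tm.vertex_normals)))
    h = h * np.where(sign == 0, 1.0, sign)
    if smooth_iters:
        e = tm.edges_unique
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                                shape=(n, n))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        for _ in range(smooth_iters):
            h = adj.dot(h) / np.maximum(deg, 1)
    return h


def count_protrusions(
    mesh: SurfaceMesh,
    curvature_quantile: float = 0.9,
    min_patch_area: float | None = None,
    curvature_floor_ratio: float = 1.5,
) -> int:
    """Count membrane protrusions as high-curvature surface patches.

    Vertices with mean curvature above the ``curvature_quantile`` of the
    mesh's own curvature distribution are flagged; flagged vertices are
    clustered into edge-connected patches; the area of each patch is the
    summed area of faces touching it, and patches with area ≥
    ``min_patch_area`` count as protrusions.

    The default minimum patch area is a spherical cap of height half a mesh
    edge length on the area-equivalent sphere (2π·r_eq·h, h = edge/2).
    Because flagging is quantile-capped, a genuine protrusion's patch area
    is roughly (1−q)·A_total divided by the number of protrusions, while
    voxel-lattice noise on a featureless region fragments into patches about
    half that size; the half-edge cap sits between the two regimes.

    Flagging additionally requires the curvature to exceed
    ``curvature_floor_ratio`` × the mesh's median curvature: a protrusion
    must be substantially more curved than the cell's overall roundness, so
    a featureless (plain-sphere) surface — where the quantile alone would
    still flag its least-round 10% — yields 0.
    """
    tm = mesh.to_trimesh()
    areas = tm.area_faces
    if np.any(areas <= 0):
        raise ValueError("degenerate mesh: zero-area faces")
    h = mesh.mean_curvature
    if h is None:
        h = vertex_mean_curvature(mesh)
        mesh.mean_curvature = h
    thresh = max(np.quantile(h, curvature_quantile),
                 curvature_floor_ratio * np.median(h))
    flagged = h > thresh
    if not flagged.any():
        return 0
    if min_patch_area is None:
        r_eq = np.sqrt(tm.area / (4.0 * np.pi))
        min_patch_area = np.pi * r_eq * float(tm.edges_unique_length.mean())
    # connected components of flagged vertices along mesh edges
    e = tm.edges_unique
    keep = flagged[e[:, 0]] & flagged[e[:, 1]]
    idx = np.flatnonzero(flagged)
    remap = -np.ones(len(tm.vertices), dtype=int)
    remap[idx] = np.arange(len(idx))
    ek = remap[e[keep]]
    adj = sparse.csr_matrix(
        (np.ones(len(ek)), (ek[:, 0], ek[:, 1])), shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(adj, directed=False)
    # patch area: faces with any vertex in the patch
    face_label = -np.ones(len(tm.faces), dtype=int)
    for v_col in range(3):
        fv = tm.faces[:, v_col]
        has = flagged[fv]
        face_label[has] = labels[remap[fv[has]]]
    count = 0
    for c in range(n_comp):
        if areas[face_label == c].sum() >= min_patch_area:
            count += 1
    return count


def morphology_record(mask: CellMask, **protrusion_kwargs) -> dict:
    """Volume, vertex count and protrusion count for one mask."""
    mesh = extract_surface(mask)
    return {
        "cell_id": mask.cell_id,
        "volume_um3": compute_volume(mask),
        "n_vertices": count_vertices(mesh),
        "n_protrusions": count_protrusions(mesh, **protrusion_kwargs),
        "surface_area_um2": mesh.area,
    }
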