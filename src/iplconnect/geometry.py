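"""Frustum rendering of annotated processes.

Each linked pair of circles becomes a closed conical frustum in physical
(nm) coordinates.  Circles with exactly two links are tilted out of the XY
plane by half the bend angle of the process at that circle, about the normal
of the plane through the three circle centres; circles with one or three or
more links stay XY-parallel.  The union of frusta approximates the cell but
captures its dendritic morphology faithfully.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import AnnotationModel, Location, VolumeMeta, physical_position

__all__ = [
    "Mesh",
    "tilt_angle",
    "frustum_mesh",
    "render_cell",
    "write_obj",
    "write_ply",
]

log = logging.getLogger("iplconnect.geometry")


@dataclass
class Mesh:
    """Triangle mesh in physical nm coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    provenance: int | None = None  # structure id

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    @staticmethod
    def concatenate(meshes: list["Mesh"], provenance: int | None = None) -> "Mesh":
        if not meshes:
            return Mesh(np.empty((0, 3)), np.empty((0, 3), dtype=int), provenance)
        verts, faces, off = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + off)
            off += len(m.vertices)
        return Mesh(np.vstack(verts), np.vstack(faces), provenance)


def tilt_angle(
    prev: Location, cur: Location, nxt: Location, meta: VolumeMeta
) -> tuple[float, np.ndarray]:
    """Tilt of the circle at ``cur`` on a 2-link process, in degrees.

    The circle is tilted from the XY plane by half the total bend angle
    between the incoming segment (prev -> cur) and the outgoing segment
    (cur -> nxt), about the normal of the plane through the three centres.
    Returns ``(angle_degrees, unit_axis)``; the axis is the zero vector for
    collinear centres (angle 0).
    """
    p = np.array(physical_position(prev, meta))
    c = np.array(physical_position(cur, meta))
    n = np.array(physical_position(nxt, meta))
    u = c - p
    v = n - c
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident circle centres")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    total = math.degrees(math.acos(cosang))
    axis = np.cross(u, v)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return 0.0, np.zeros(3)
    return total / 2.0, axis / norm


def _rotation_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    if degrees == 0.0 or np.allclose(axis, 0):
        return np.eye(3)
    th = math.radians(degrees)
    kx, ky, kz = axis
    k = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(th) * k + (1 - math.cos(th)) * (k @ k)


def _rim(center: np.ndarray, radius_nm: float, n_sides: int, rot: np.ndarray) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n_sides) / n_sides
    disk = np.stack(
        [radius_nm * np.cos(theta), radius_nm * np.sin(theta), np.zeros(n_sides)], axis=1
    )
    return center + disk @ rot.T


def frustum_mesh(
    a: Location,
    b: Location,
    meta: VolumeMeta,
    n_sides: int = 16,
    tilt_a: tuple[float, np.ndarray] | None = None,
    tilt_b: tuple[float, np.ndarray] | None = None,
) -> Mesh:
    """Closed frustum joining circles ``a`` and ``b`` in physical nm.

    Each rim is an ``n_sides``-gon in its circle's plane (XY unless a tilt
    is given); the lateral surface and two end caps are triangulated, giving
    ``2 * n_sides + 2`` vertices and ``4 * n_sides`` faces.  Rim vertices
    share angular offsets so the lateral surface is not twisted.
    """
    if n_sides < 3:
        raise ValueError("n_sides must be >= 3")
    ca = np.array(physical_position(a, meta))
    cb = np.array(physical_position(b, meta))
    if np.allclose(ca, cb):
        raise ValueError("zero physical separation between linked circles")
    rot_a = _rotation_matrix(*reversed(tilt_a)) if tilt_a else np.eye(3)
    rot_b = _rotation_matrix(*reversed(tilt_b)) if tilt_b else np.eye(3)
    rim_a = _rim(ca, a.radius * meta.pixel_size_nm, n_sides, rot_a)
    rim_b = _rim(cb, b.radius * meta.pixel_size_nm, n_sides, rot_b)

    verts = np.vstack([rim_a, rim_b, ca[None, :], cb[None, :]])
    ia = np.arange(n_sides)
    ja = (ia + 1) % n_sides
    ib, jb = ia + n_sides, ja + n_sides
    lateral = np.concatenate(
        [np.stack([ia, ib, jb], axis=1), np.stack([ia, jb, ja], axis=1)]
    )
    cap_a = np.stack([np.full(n_sides, 2 * n_sides), ja, ia], axis=1)
    cap_b = np.stack([np.full(n_sides, 2 * n_sides + 1), ib, jb], axis=1)
    return Mesh(verts, np.vstack([lateral, cap_a, cap_b]))


def render_cell(
    model: AnnotationModel,
    cell_id: int,
    n_sides: int = 16,
    weld: bool = False,
    include_children: bool = False,
) -> Mesh:
    """Render a cell as the union of frusta over its location links.

    Circles with exactly two links get the half-angle tilt; others stay
    XY-parallel.  A structure with locations but no links yields isolated
    disks (degenerate frusta are impossible since linked circles must sit
    on different slices) and logs a warning.  With ``weld=True`` coincident
    vertices of adjoining frusta are merged.
    """
    sids = {cell_id}
    if include_children:
        sids |= {c.id for c in model.children_of(cell_id)}
    locs = {l.id: l for l in model.locations.values() if l.structure_id in sids}
    links = [
        ll
        for ll in model.location_links
        if ll.a in locs and ll.b in locs
    ]

    neighbors: dict[int, list[int]] = {lid: [] for lid in locs}
    for ll in links:
        neighbors[ll.a].append(ll.b)
        neighbors[ll.b].append(ll.a)

    tilts: dict[int, tuple[float, np.ndarray]] = {}
    for lid, nbrs in neighbors.items():
        if len(nbrs) == 2:
            p, n = sorted(nbrs)
            try:
                tilts[lid] = tilt_angle(locs[p], locs[lid], locs[n], model.meta)
            except ValueError:
                tilts[lid] = (0.0, np.zeros(3))

    meshes = []
    if not links and locs:
        log.warning("structure %d has locations but no links; emitting isolated disks", cell_id)
        for lid in sorted(locs):
            meshes.append(_disk_mesh(locs[lid], model.meta, n_sides))
    for ll in sorted((min(l.a, l.b), max(l.a, l.b)) for l in links):
        a, b = locs[ll[0]], locs[ll[1]]
        meshes.append(
            frustum_mesh(a, b, model.meta, n_sides, tilts.get(a.id), tilts.get(b.id))
        )
    mesh = Mesh.concatenate(meshes, provenance=cell_id)
    if weld and len(mesh.vertices):
        mesh = _weld(mesh)
    return mesh


def _disk_mesh(loc: Location, meta: VolumeMeta, n_sides: int) -> Mesh:
    c = np.array(physical_position(loc, meta))
    rim = _rim(c, loc.radius * meta.pixel_size_nm, n_sides, np.eye(3))
    verts = np.vstack([rim, c[None, :]])
    i = np.arange(n_sides)
    faces = np.stack([np.full(n_sides, n_sides), i, (i + 1) % n_sides], axis=1)
    return Mesh(verts, faces, provenance=loc.structure_id)


def _weld(mesh: Mesh, tol: float = 1e-6) -> Mesh:
    key = np.round(mesh.vertices / tol).astype(np.int64)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    first = np.full(len(uniq), -1, dtype=int)
    for i, g in enumerate(inverse):
        if first[g] < 0:
            first[g] = i
    verts = mesh.vertices[first]
    remap = inverse
    faces = remap[mesh.faces]
    # drop faces that collapsed
    keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return Mesh(verts, faces[keep], provenance=mesh.provenance)


def write_obj(mesh: Mesh, path: str | Path, name: str | None = None) -> Path:
    """Write a triangulated Wavefront OBJ (1-based indices)."""
    path = Path(path)
    lines = [f"o {name or ('structure_' + str(mesh.provenance))}"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ply(mesh: Mesh, path: str | Path) -> Path:
    """Write an ASCII PLY file."""
    path = Path(path)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")
    return path
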