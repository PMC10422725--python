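"""Triangle-mesh substrate: I/O, watertight volume, plane cuts with caps.

All geometry is in millimetres. Meshes are plain indexed vertex/face
arrays; ``trimesh`` is used for STL/PLY parsing and for splitting
triangles at a cutting plane, while the watertight bookkeeping (edge
manifold check, divergence-theorem volume, cap triangulation) is done
here so that cut volumes are exactly conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "Plane",
    "MeshPair",
    "MeshError",
    "ValidationError",
    "read_mesh",
    "write_mesh",
    "mesh_volume",
    "plane_from_points",
    "cut_mesh",
]

#: vertices closer than this (mm) are considered coincident on read/clean
MERGE_TOLERANCE = 1e-6


class MeshError(Exception):
    """Base class for mesh-layer failures."""


class ValidationError(MeshError):
    """Input violates a documented precondition."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm.

    ``provenance`` is a free-text label carried through the pipeline
    (tooth id, timepoint, processing step) so intermediate meshes stay
    identifiable in logs and manifests.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max(initial=-1) >= len(self.vertices):
            raise ValidationError("face index out of range")
        if len(self.faces) and self.faces.min(initial=0) < 0:
            raise ValidationError("negative face index")

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, provenance: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.provenance if provenance is None else provenance,
        )

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals and face areas (mm^2)."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        normals = np.zeros_like(cross)
        ok = area2 > 0
        normals[ok] = cross[ok] / area2[ok, None]
        return normals, area2 / 2.0

    def open_edge_count(self) -> int:
        """Number of undirected edges not shared by exactly two faces."""
        if not len(self.faces):
            return 0
        edges = np.sort(_directed_edges(self.faces), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_watertight(self) -> bool:
        """Edge-manifold and consistently oriented.

        Every undirected edge must be shared by exactly two faces and every
        directed edge must appear exactly once (consistent winding).
        """
        if not len(self.faces):
            return False
        directed = _directed_edges(self.faces)
        _, d_counts = np.unique(directed, axis=0, return_counts=True)
        if (d_counts != 1).any():
            return False
        return self.open_edge_count() == 0

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def cleaned(self, merge_tol: float = MERGE_TOLERANCE) -> "TriangleMesh":
        """Merge coincident vertices and drop degenerate faces."""
        v, f = _merge_vertices(self.vertices, self.faces, merge_tol)
        f = _drop_degenerate(v, f)
        v, f = _drop_unreferenced(v, f)
        return TriangleMesh(v, f, self.provenance)


@dataclass
class Plane:
    """Oriented plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValidationError("plane normal has zero length")
        self.normal = n / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return (pts - self.point) @ self.normal

    def oriented_toward(self, reference: np.ndarray) -> "Plane":
        """Return a copy whose positive side contains ``reference``."""
        if self.signed_distance(reference)[0] < 0:
            return Plane(self.point.copy(), -self.normal)
        return Plane(self.point.copy(), self.normal.copy())


@dataclass
class MeshPair:
    """T0/T1 surface models of one tooth."""

    t0: TriangleMesh
    t1: TriangleMesh
    tooth_id: str = ""
    side: str = ""
    arch: str = ""


# ---------------------------------------------------------------------------
# helpers

def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    if not len(vertices):
        return vertices, faces
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if not len(pairs):
        return vertices, faces
    # union-find over coincident pairs
    parent = np.arange(len(vertices))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    root = np.array([find(i) for i in range(len(vertices))])
    uniq, inverse = np.unique(root, return_inverse=True)
    return vertices[uniq], inverse[faces]


def _drop_degenerate(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if not len(faces):
        return faces
    combinatorial = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 2] == faces[:, 0])
    )
    tri = vertices[faces]
    area2 = np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return faces[~combinatorial & (area2 > 2e-12)]


def _drop_unreferenced(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if not len(faces):
        return vertices[:0], faces
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[faces]


# ---------------------------------------------------------------------------
# I/O

def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read an STL or PLY surface model (binary or ASCII dialects).

    The raw mesh is cleaned: per-facet duplicated vertices (as stored by
    STL) are merged within ``MERGE_TOLERANCE`` mm and degenerate faces
    dropped. Units are assumed to be mm.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    try:
        tm = trimesh.load(path, file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - surface parse errors uniformly
        raise MeshError(f"cannot read mesh from {path!r}: {exc}") from exc
    mesh = TriangleMesh(tm.vertices, tm.faces, provenance=path).cleaned()
    if mesh.n_faces == 0:
        raise ValidationError(f"mesh at {path!r} is empty after cleaning")
    return mesh


def write_mesh(
    mesh: TriangleMesh,
    path,
    fmt: str | None = None,
    scalars: np.ndarray | None = None,
    tolerance: float = 0.3,
    clip_range: float = 0.5,
) -> None:
    """Write STL (binary) or PLY; with ``scalars`` a PLY colour map.

    ``scalars`` are per-vertex signed deviations (mm) encoded as uchar RGB
    via the deviation colormap (green within the tolerance band, blue/red
    ramps outside, clamped at ``clip_range``).
    """
    if mesh.n_faces == 0:
        raise ValidationError("refusing to write an empty mesh")
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    tm = mesh.to_trimesh()
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float64).reshape(-1)
        if len(scalars) != mesh.n_vertices:
            raise ValidationError("need one scalar per vertex")
        if fmt != "ply":
            raise ValidationError("per-vertex colours require PLY output")
        from .root_analysis import deviation_colors  # local: avoid cycle

        rgb = deviation_colors(scalars, tolerance=tolerance, clip_range=clip_range)
        tm.visual.vertex_colors = np.column_stack(
            [rgb, np.full(len(rgb), 255, dtype=np.uint8)]
        )
    try:
        tm.export(path, file_type=fmt)
    except Exception as exc:  # noqa: BLE001
        raise MeshError(f"cannot write mesh to {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# volume

def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem.

    Sum of signed tetrahedron volumes against the origin; positive for
    outward-oriented surfaces, negative if the winding is inverted
    (the sign is returned as-is so callers can detect orientation).
    Raises for non-watertight input, naming the open-edge count.
    """
    if not mesh.is_watertight():
        raise ValidationError(
            f"volume of a non-watertight mesh is undefined "
            f"({mesh.open_edge_count()} open/non-manifold edges)"
        )
    tri = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


# ---------------------------------------------------------------------------
# planes and cutting

def plane_from_points(p1, p2, p3, toward: np.ndarray | None = None) -> Plane:
    """Plane through three non-collinear points.

    Three unordered points do not define a signed normal; when ``toward``
    is given (e.g. the occlusal cusp landmark) the normal is oriented so
    that point lies on the positive side.
    """
    p1, p2, p3 = (np.asarray(p, dtype=np.float64).reshape(3) for p in (p1, p2, p3))
    cross = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(cross) / 2.0 <= 1e-9:
        raise ValidationError("points are collinear; no unique plane")
    plane = Plane(p1, cross)
    if toward is not None:
        plane = plane.oriented_toward(np.asarray(toward, dtype=np.float64))
    return plane


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary of an oriented mesh."""
    directed = _directed_edges(faces)
    undirected = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    boundary = directed[counts[inverse] == 1]
    nxt = {}
    for a, b in boundary:
        if int(a) in nxt:
            raise MeshError("pinched boundary (vertex on two loops); cannot cap")
        nxt[int(a)] = int(b)
    loops: list[np.ndarray] = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            if cur not in nxt:
                raise MeshError("open boundary chain; cannot cap")
            cur = nxt.pop(cur)
        nxt.pop(start, None)
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _cap_loops(vertices: np.ndarray, faces: np.ndarray, outward: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Close every boundary loop with a centroid fan oriented along ``outward``.

    A fan from the loop centroid stays watertight for the near-convex
    cross-sections produced by cervical/apical plane cuts, including the
    multi-loop case of a multi-rooted tooth (one loop per root).
    """
    loops = _boundary_loops(faces)
    if not loops:
        return vertices, faces
    new_faces = [faces]
    verts = [vertices]
    n = len(vertices)
    for loop in loops:
        centroid = vertices[loop].mean(axis=0)
        verts.append(centroid[None, :])
        idx = np.arange(len(loop))
        tris = np.column_stack(
            [np.full(len(loop), n), loop[idx], loop[(idx + 1) % len(loop)]]
        )
        # orient the fan so its normal points along the outward direction
        tri = np.concatenate([centroid[None, :], vertices[loop[:2]]], axis=0)
        normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        if float(normal @ outward) < 0:
            tris = tris[:, [0, 2, 1]]
        new_faces.append(tris)
        n += 1
    return np.concatenate(verts, axis=0), np.concatenate(new_faces, axis=0)


def cut_mesh(
    mesh: TriangleMesh,
    plane: Plane,
    keep: str = "above",
    cap: bool = True,
) -> TriangleMesh:
    """Cut a watertight mesh by a plane, keeping one closed half.

    ``keep="above"`` keeps the positive side of the plane normal.
    Crossing triangles are split exactly at the plane; with ``cap=True``
    each cut boundary loop is closed by a planar fan so the output is
    watertight again. An empty result (plane misses the mesh) is legal
    and returned as an empty mesh.
    """
    if keep not in ("above", "below"):
        raise ValidationError("keep must be 'above' or 'below'")
    if not mesh.is_watertight():
        raise ValidationError(
            f"cut requires a watertight mesh ({mesh.open_edge_count()} open edges)"
        )
    # vertices lying exactly on the plane pinch the cut boundary into
    # touching loops; nudge the plane deterministically just past them
    # (sub-merge-tolerance, so the geometry is unaffected in practice)
    point = plane.point
    dist = (mesh.vertices - point) @ plane.normal
    eps = 2.0 * MERGE_TOLERANCE
    shift = 0.0
    for _ in range(200):
        if not np.any(np.abs(dist - shift) < eps):
            break
        shift += 2.5 * eps
    else:  # pragma: no cover - would need 200 coincident levels
        raise MeshError("cannot find a clear cutting level near the plane")
    if shift:
        point = point + shift * plane.normal
    plane = Plane(point, plane.normal)
    normal = plane.normal if keep == "above" else -plane.normal
    side = (mesh.vertices - plane.point) @ normal
    if (side >= 0).all():
        return mesh.copy()
    if (side <= 0).all():
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), mesh.provenance)
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh.to_trimesh(), normal, plane.point, cap=False
    )
    v, f = np.asarray(sliced.vertices), np.asarray(sliced.faces)
    v, f = _merge_vertices(v, f, MERGE_TOLERANCE)
    f = _drop_degenerate(v, f)
    v, f = _drop_unreferenced(v, f)
    if cap and len(f):
        v, f = _cap_loops(v, f, -normal)
    out = TriangleMesh(v, f, mesh.provenance)
    if cap and len(f) and not out.is_watertight():  # pragma: no cover - defensive
        raise MeshError("capped cut failed to close the surface")
    return out
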