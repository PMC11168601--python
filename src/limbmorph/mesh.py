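"""Core triangle-mesh types and geometric operations.

All coordinates are millimetres in the scanner/global frame. Faces are
vertex-index triples wound counter-clockwise when viewed from outside
(outward-pointing implied normals).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import trimesh as _trimesh

from .exceptions import MeshValidationError

__all__ = [
    "TriangleMesh",
    "Plane",
    "RigidTransform",
    "LandmarkPairs",
    "ValidationReport",
    "validate_mesh",
    "merge_meshes",
    "vertex_normals",
    "apply_transform",
    "extreme_point",
    "anatomical_trim_plane",
    "trim_by_plane",
    "median_edge_length",
]


@dataclass
class TriangleMesh:
    """A triangulated surface: shared-vertex list plus index faces.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) integer array of vertex indices, CCW = outward.
    name : free-text label, e.g. ``"skin_hands_on"`` or ``"hard_tissue"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def with_name(self, name: str) -> "TriangleMesh":
        return replace(self, name=name)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh, name: str = "") -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name)


@dataclass(frozen=True)
class Plane:
    """Oriented plane; ``normal`` points toward the half-space that is kept."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64).reshape(3))
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise ValueError(f"plane normal must be unit length, got |n| = {norm!r}")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive on the kept side of the plane."""
        pts = np.asarray(points, dtype=np.float64)
        return (pts - self.point) @ self.normal


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion v -> R v + t (rotation + translation, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation matrix is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix, row-major."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


@dataclass(frozen=True)
class LandmarkPairs:
    """Index-paired 3-D points picked on equivalent anatomy of two models."""

    source_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.source_points, dtype=np.float64).reshape(-1, 3)
        dst = np.asarray(self.target_points, dtype=np.float64).reshape(-1, 3)
        if len(src) != len(dst):
            raise ValueError(
                f"landmark counts differ: {len(src)} source vs {len(dst)} target"
            )
        if len(src) < 3:
            raise ValueError(f"need at least 3 landmark pairs, got {len(src)}")
        object.__setattr__(self, "source_points", src)
        object.__setattr__(self, "target_points", dst)

    def __len__(self) -> int:
        return len(self.source_points)


class ValidationReport(NamedTuple):
    mesh: TriangleMesh
    n_vertices_removed: int
    n_faces_removed: int


def validate_mesh(mesh: TriangleMesh, prune: bool = False) -> ValidationReport:
    """Check TriangleMesh invariants, optionally pruning fixable defects.

    Without ``prune`` any violation raises :class:`MeshValidationError`
    naming the offending face or vertex. With ``prune``, unreferenced
    vertices and degenerate faces (a repeated vertex index) are removed
    and face indices remapped; out-of-range indices and non-finite
    coordinates are never repairable and always raise.
    """
    v, f = mesh.vertices, mesh.faces

    bad_coord = ~np.isfinite(v).all(axis=1)
    if bad_coord.any():
        raise MeshValidationError(
            f"non-finite coordinate at vertex {int(np.flatnonzero(bad_coord)[0])}"
        )
    if len(f):
        out_of_range = (f < 0) | (f >= len(v))
        if out_of_range.any():
            face_idx = int(np.flatnonzero(out_of_range.any(axis=1))[0])
            raise MeshValidationError(
                f"face {face_idx} references vertex index out of range "
                f"(mesh has {len(v)} vertices): {f[face_idx].tolist()}"
            )

    degenerate = np.zeros(len(f), dtype=bool)
    if len(f):
        degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    n_faces_removed = 0
    if degenerate.any():
        if not prune:
            raise MeshValidationError(
                f"face {int(np.flatnonzero(degenerate)[0])} repeats a vertex index"
            )
        n_faces_removed = int(degenerate.sum())
        f = f[~degenerate]

    referenced = np.zeros(len(v), dtype=bool)
    if len(f):
        referenced[f.ravel()] = True
    n_unref = int((~referenced).sum())
    n_vertices_removed = 0
    if n_unref and prune:
        remap = np.cumsum(referenced) - 1
        v = v[referenced]
        f = remap[f]
        n_vertices_removed = n_unref
    elif n_unref and not prune:
        raise MeshValidationError(
            f"{n_unref} unreferenced vertices (first: vertex "
            f"{int(np.flatnonzero(~referenced)[0])}); re-run with prune=True"
        )

    return ValidationReport(TriangleMesh(v, f, mesh.name), n_vertices_removed, n_faces_removed)


def merge_meshes(meshes: Sequence[TriangleMesh], name: str = "") -> TriangleMesh:
    """Concatenate surfaces into one mesh, offsetting face indices.

    This mirrors compiling separately segmented structures (bones,
    meniscus/patellar-tendon assembly) into a single hard-tissue surface
    file: pure concatenation, no boolean union, no vertex welding.
    """
    meshes = list(meshes)
    if not meshes:
        raise ValueError("merge_meshes requires at least one mesh")
    offsets = np.cumsum([0] + [m.n_vertices for m in meshes[:-1]])
    vertices = np.vstack([m.vertices for m in meshes])
    faces = np.vstack([m.faces + off for m, off in zip(meshes, offsets)])
    return TriangleMesh(vertices, faces, name or "+".join(m.name for m in meshes))


class VertexNormals(NamedTuple):
    normals: np.ndarray  # (n, 3) unit vectors; zero rows where undefined
    undefined: np.ndarray  # (n,) bool, True where no incident face area


def vertex_normals(mesh: TriangleMesh) -> VertexNormals:
    """Area-weighted per-vertex outward unit normals.

    Each vertex normal is the sum of incident face normals weighted by
    face area (i.e. the sum of un-normalized edge cross products),
    normalized to unit length. Vertices with no incident faces (or zero
    total area) get a zero vector and are flagged ``undefined``.
    """
    v, f = mesh.vertices, mesh.faces
    acc = np.zeros_like(v)
    if len(f):
        # cross product of edge vectors = 2 * area * unit normal
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        fn = np.cross(e1, e2)
        for k in range(3):
            np.add.at(acc, f[:, k], fn)
    norms = np.linalg.norm(acc, axis=1)
    undefined = norms < 1e-300
    out = np.zeros_like(acc)
    ok = ~undefined
    out[ok] = acc[ok] / norms[ok, None]
    return VertexNormals(out, undefined)


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Map every vertex through the rigid motion; connectivity unchanged."""
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


class ExtremePoint(NamedTuple):
    point: np.ndarray
    index: int


def extreme_point(mesh: TriangleMesh, direction: np.ndarray) -> ExtremePoint:
    """Vertex with maximal projection onto ``direction``.

    Ties are broken by lowest vertex index (``argmax`` first occurrence),
    so results are deterministic on symmetric meshes.
    """
    if mesh.n_vertices == 0:
        raise ValueError("extreme_point of an empty mesh")
    d = np.asarray(direction, dtype=np.float64).reshape(3)
    n = np.linalg.norm(d)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("direction must be a non-degenerate 3-vector")
    idx = int(np.argmax(mesh.vertices @ (d / n)))
    return ExtremePoint(mesh.vertices[idx].copy(), idx)


def anatomical_trim_plane(
    reference_mesh: TriangleMesh,
    distal_direction: np.ndarray = (0.0, 0.0, -1.0),
    offset_mm: float = 50.0,
) -> Plane:
    """Trim plane a fixed distance proximal to the reference's most distal point.

    The standard protocol trims both the hard-tissue and skin surfaces
    50 mm proximally to the most distal bony point, keeping the distal
    (socket-encapsulated) region; the same plane, expressed in the global
    frame, is reused for both surfaces. The plane normal is the distal
    direction so the kept half-space is distal.
    """
    if not offset_mm > 0:
        raise ValueError(f"offset_mm must be positive, got {offset_mm}")
    d = np.asarray(distal_direction, dtype=np.float64).reshape(3)
    n = np.linalg.norm(d)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("distal_direction is degenerate")
    d = d / n
    distal_pt = extreme_point(reference_mesh, d).point
    return Plane(point=distal_pt - offset_mm * d, normal=d)


def trim_by_plane(mesh: TriangleMesh, plane: Plane) -> TriangleMesh:
    """Keep geometry on the plane's normal side, splitting crossing triangles.

    Triangles intersecting the plane are cut at exact edge-plane
    intersections so the boundary lies on the plane; the cut is left open
    (no cap), matching distance analysis on open scanned surfaces. A mesh
    entirely on the discarded side yields an empty mesh with a warning.
    """
    tm = mesh.to_trimesh()
    cut = _trimesh.intersections.slice_mesh_plane(
        tm, plane_normal=plane.normal, plane_origin=plane.point, cap=False
    )
    out = TriangleMesh.from_trimesh(cut, mesh.name)
    if out.n_vertices == 0:
        warnings.warn(
            f"trim_by_plane: mesh {mesh.name!r} lies entirely on the discarded "
            "side of the plane; result is empty",
            stacklevel=2,
        )
        return out
    # snap numerical stragglers onto the plane so the signed-distance
    # invariant (>= -1e-9 mm) holds exactly
    sd = plane.signed_distance(out.vertices)
    behind = sd < 0
    if behind.any():
        if sd.min() < -1e-9:
            raise MeshValidationError(
                f"trim produced a vertex {-sd.min():.3e} mm beyond the plane"
            )
        out.vertices[behind] -= sd[behind, None] * plane.normal
    return out


def median_edge_length(mesh: TriangleMesh) -> float:
    """Median length of unique mesh edges (mm); the natural discretization scale."""
    f = mesh.faces
    if len(f) == 0:
        raise ValueError("mesh has no faces")
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    return float(np.median(lengths))
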