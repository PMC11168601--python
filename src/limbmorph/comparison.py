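"""Signed skin-to-skin comparison between two registered interface conditions.

After the two scans are registered on a common bone, each reference-skin
vertex is compared with the nearest vertex of the other condition's skin.
Projecting the offset onto the reference outward normal gives a sign:
negative where the other skin lies inward (toward bone), i.e. where the
other interface is more compressive; positive where the fit is more
relaxed. The unsigned nearest distance is retained alongside.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .distance import nearest_vertex_distances
from .exceptions import OrientationError
from .io import ScalarMesh
from .mesh import TriangleMesh, median_edge_length, merge_meshes, vertex_normals

__all__ = [
    "SignedComparisonField",
    "signed_skin_difference",
    "bidirectional_comparison",
    "comparison_summary",
    "overlay_surfaces",
]


@dataclass
class SignedComparisonField:
    """Per-reference-vertex signed offset to the other condition's skin.

    ``signed_offsets[i] < 0`` means the other interface is more
    compressive at reference vertex i. ``boundary_flag`` marks vertices
    near an open (trim) boundary, where nearest-neighbour matches across
    the open edge are unreliable; they stay in heat maps but are excluded
    from summary statistics.
    """

    reference_name: str
    other_name: str
    signed_offsets: np.ndarray
    unsigned_distances: np.ndarray
    nearest_index: np.ndarray
    boundary_flag: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.signed_offsets)
        for name in ("unsigned_distances", "nearest_index", "boundary_flag"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != signed_offsets length")

    def __len__(self) -> int:
        return len(self.signed_offsets)

    def to_scalar_mesh(self, reference: TriangleMesh) -> ScalarMesh:
        return ScalarMesh(
            mesh=reference, scalars=self.signed_offsets, scalar_name="signed_offset_mm"
        )


def _boundary_flags(mesh: TriangleMesh) -> np.ndarray:
    """Vertices within one median edge length of an open-boundary vertex."""
    f = mesh.faces
    flags = np.zeros(mesh.n_vertices, dtype=bool)
    if len(f) == 0:
        return flags
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    open_edges = uniq[counts == 1]
    if len(open_edges) == 0:
        return flags
    boundary_vertices = np.unique(open_edges)
    tree = cKDTree(mesh.vertices[boundary_vertices])
    near = tree.query_ball_point(mesh.vertices, median_edge_length(mesh))
    flags[[i for i, lst in enumerate(near) if lst]] = True
    return flags


def signed_skin_difference(
    reference: TriangleMesh, other: TriangleMesh
) -> SignedComparisonField:
    """Signed offset from each reference-skin vertex to the nearest other-skin vertex.

    Requires both skins already registered into a common frame and the
    reference consistently oriented outward. For vertex v with outward
    normal n and nearest other vertex w: signed = (w - v)·n, so
    |signed| <= |w - v| always, and negative means the other surface sits
    inward of the reference.
    """
    normals, undefined = vertex_normals(reference)
    if reference.n_vertices and undefined.mean() > 0.01:
        raise OrientationError(
            f"reference {reference.name!r} has {int(undefined.sum())} vertices "
            "with undefined normals (>1%); orient/clean the surface first"
        )
    field = nearest_vertex_distances(reference, other)
    w = other.vertices[field.nearest_index]
    signed = np.einsum("ij,ij->i", w - reference.vertices, normals)
    return SignedComparisonField(
        reference_name=reference.name,
        other_name=other.name,
        signed_offsets=signed,
        unsigned_distances=field.distances,
        nearest_index=field.nearest_index,
        boundary_flag=_boundary_flags(reference),
    )


def bidirectional_comparison(
    skin_a: TriangleMesh, skin_b: TriangleMesh
) -> tuple[SignedComparisonField, SignedComparisonField]:
    """Compare both ways with a consistent sign convention.

    The comparison is run with each skin as reference; the second field's
    sign is inverted so that on *both* maps negative consistently means
    skin_b's interface is more compressive (the second heat map is the
    "inverted" one).
    """
    field_a = signed_skin_difference(skin_a, skin_b)
    field_b = signed_skin_difference(skin_b, skin_a)
    field_b.signed_offsets = -field_b.signed_offsets
    return field_a, field_b


def comparison_summary(field: SignedComparisonField) -> dict:
    """Mean/extreme signed offsets, boundary-flagged vertices excluded."""
    ok = ~field.boundary_flag
    s = field.signed_offsets[ok]
    if len(s) == 0:
        raise ValueError("all vertices are boundary-flagged; nothing to summarize")
    return {
        "reference": field.reference_name,
        "other": field.other_name,
        "n_vertices": len(field),
        "n_boundary_flagged": int(field.boundary_flag.sum()),
        "mean_signed_offset_mm": float(s.mean()),
        "min_signed_offset_mm": float(s.min()),
        "max_signed_offset_mm": float(s.max()),
        "percent_compressive": float((s < 0).mean() * 100.0),
        "mean_unsigned_distance_mm": float(field.unsigned_distances[ok].mean()),
    }


def overlay_surfaces(skin_a: TriangleMesh, skin_b: TriangleMesh) -> ScalarMesh:
    """Both skins in one scene with a 0/1 condition label per vertex.

    Lets a viewer overlay the two surface topologies directly, colouring
    by condition.
    """
    merged = merge_meshes([skin_a, skin_b], name=f"{skin_a.name}|{skin_b.name}")
    labels = np.concatenate(
        [np.zeros(skin_a.n_vertices), np.ones(skin_b.n_vertices)]
    )
    return ScalarMesh(mesh=merged, scalars=labels, scalar_name="condition")
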