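"""Rigid alignment of bone models between two scan conditions.

Two skin surfaces from separate scans live in different scanner frames; a
common internal bone (the tibia) provides the bridge. Alignment proceeds
in two stages, mirroring standard surface-comparison practice: a coarse
least-squares fit on manually picked equivalent point pairs, then
iterative-closest-point (ICP) refinement on the bone surfaces. Quality is
quantified with bidirectional Hausdorff metrics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .distance import nearest_vertex_distances
from .exceptions import LandmarkError, RegistrationError
from .mesh import LandmarkPairs, RigidTransform, TriangleMesh

__all__ = [
    "ICPParams",
    "LandmarkFitResult",
    "ICPResult",
    "HausdorffReport",
    "landmark_rigid_fit",
    "icp_refine",
    "hausdorff_report",
]


@dataclass(frozen=True)
class ICPParams:
    """Knobs of the point-to-point ICP refinement.

    max_pair_distance rejects correspondences farther than the cutoff
    (mm); ``None`` accepts all. ``subsample`` caps the number of source
    vertices used (drawn once, seeded, so the RMS trace stays monotone).
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-6  # mm, RMS change between iterations
    max_pair_distance: float | None = None
    subsample: int | None = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass(frozen=True)
class LandmarkFitResult:
    transform: RigidTransform
    residuals: np.ndarray  # per-pair |T(src) - dst|, mm
    rms: float


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform  # composed: includes the initial transform
    rms_trace: np.ndarray  # correspondence RMS (mm) per iteration
    converged: bool

    @property
    def n_iterations(self) -> int:
        return len(self.rms_trace)

    @property
    def final_rms(self) -> float:
        return float(self.rms_trace[-1])


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid motion src -> dst (no scale, no reflection)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dc, src - sc)
    R = rot.as_matrix()
    return RigidTransform(R, dc - R @ sc)


def landmark_rigid_fit(pairs: LandmarkPairs) -> LandmarkFitResult:
    """Orthogonal-Procrustes rigid fit of paired landmarks.

    Minimizes the sum of squared distances between transformed source
    points and their paired targets over rotations and translations;
    the determinant is constrained to +1 so anatomy is never mirrored.
    Collinear source points leave a rotation axis unconstrained and are
    rejected.
    """
    src, dst = pairs.source_points, pairs.target_points
    centered = src - src.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise LandmarkError(
            "source landmarks are collinear; rigid fit is degenerate"
        )
    t = _kabsch(src, dst)
    residuals = np.linalg.norm(t.apply(src) - dst, axis=1)
    return LandmarkFitResult(t, residuals, float(np.sqrt(np.mean(residuals**2))))


def icp_refine(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    params: ICPParams = ICPParams(),
) -> ICPResult:
    """Point-to-point ICP on mesh vertices, starting from ``init``.

    Iterates (nearest correspondence, Kabsch fit, update) until the RMS
    correspondence distance changes by less than ``convergence_tol`` or
    ``max_iterations`` is reached. The returned transform composes the
    refinement with ``init``; the RMS trace is non-increasing.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("ICP requires non-empty meshes")
    T = init if init is not None else RigidTransform.identity()
    pts = source.vertices
    if params.subsample is not None and len(pts) > params.subsample:
        rng = np.random.default_rng(params.seed)
        pts = pts[rng.choice(len(pts), params.subsample, replace=False)]
    tree = cKDTree(target.vertices)
    trace: list[float] = []
    converged = False
    prev_rms = np.inf
    for _ in range(params.max_iterations):
        moved = T.apply(pts)
        d, idx = tree.query(moved, k=1)
        if params.max_pair_distance is not None:
            keep = d <= params.max_pair_distance
            if keep.sum() < 3:
                raise RegistrationError(
                    f"only {int(keep.sum())} correspondences within "
                    f"max_pair_distance={params.max_pair_distance} mm"
                )
        else:
            keep = slice(None)
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        trace.append(rms)
        if prev_rms - rms < params.convergence_tol:
            converged = True
            break
        T = _kabsch(moved[keep], target.vertices[idx[keep]]).compose(T)
        prev_rms = rms
    return ICPResult(T, np.asarray(trace), converged)


@dataclass(frozen=True)
class HausdorffReport:
    """Bidirectional Hausdorff similarity metrics between two surfaces.

    ``absolute_bidirectional`` is the classic Hausdorff distance: the
    larger of the two directed maxima of nearest-vertex distances.
    ``average_bidirectional`` is the mean of all nearest distances pooled
    over both directions — the symmetric mean-surface-distance convention.
    """

    directed_max_ab: float
    directed_max_ba: float
    absolute_bidirectional: float
    average_bidirectional: float
    n_a: int
    n_b: int

    def as_dict(self) -> dict:
        return {
            "directed_max_ab_mm": self.directed_max_ab,
            "directed_max_ba_mm": self.directed_max_ba,
            "absolute_bidirectional_mm": self.absolute_bidirectional,
            "average_bidirectional_mm": self.average_bidirectional,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def hausdorff_report(a: TriangleMesh, b: TriangleMesh) -> HausdorffReport:
    """Absolute and average bidirectional Hausdorff distances (vertex-based)."""
    dab = nearest_vertex_distances(a, b).distances
    dba = nearest_vertex_distances(b, a).distances
    return HausdorffReport(
        directed_max_ab=float(dab.max()),
        directed_max_ba=float(dba.max()),
        absolute_bidirectional=float(max(dab.max(), dba.max())),
        average_bidirectional=float(np.concatenate([dab, dba]).mean()),
        n_a=a.n_vertices,
        n_b=b.n_vertices,
    )
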