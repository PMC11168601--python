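"""Parametric transtibial residual-limb phantom with analytic ground truth.

The phantom stands in for segmented MRI surfaces: a tapered soft-tissue
envelope ("skin") with a hemispherical distal cap encloses a capsule
"bone", both as watertight, outward-oriented triangle meshes in a shared
frame (mm, distal = -z). In the cylindrical shaft region the bone-to-skin
clearance has a closed form, so every downstream computation can be
checked against analytic truth.

Interface conditions are emulated by radial deformation fields applied to
the skin: a near-uniform inward compression for the hands-off
(pressure-cast) condition, and a firmer overall fit with deep localized
indentations — patellar bar, medial/lateral supracondylar depressions and
a compressive distal cup — for the hands-on (rectified PTB) condition.
The exact per-vertex displacement is returned as ground truth.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import PhantomError
from .mesh import LandmarkPairs, RigidTransform, TriangleMesh, extreme_point
from . import io as lio

__all__ = [
    "PhantomSpec",
    "GaussianPatch",
    "DeformationSpec",
    "PhantomTruth",
    "generate_phantom_limb",
    "generate_multibone_hard_tissue",
    "apply_socket_deformation",
    "apply_rigid_perturbation",
    "phantom_landmarks",
    "export_phantom_set",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the undeformed limb phantom (mm).

    The skin envelope tapers from ``skin_radius_proximal`` at the open
    proximal end (z = limb_length) to ``skin_radius_distal`` at z = 0,
    closed distally by a hemisphere (pole at z = -skin_radius_distal) and
    proximally by a flat disk. The bone is a capsule of ``bone_radius``
    along the z axis between ``bone_distal_z`` and ``bone_proximal_z``
    (hemisphere centres).
    """

    limb_length: float = 160.0
    bone_radius: float = 15.0
    skin_radius_proximal: float = 50.0
    skin_radius_distal: float = 40.0
    bone_distal_z: float = 10.0
    bone_proximal_z: float = 140.0
    #: low-order angular modulation of the skin cross-section: real limb
    #: sections are roughly elliptical (cos 2θ) with a tibial-crest
    #: prominence (cos 3θ), not circular. Amplitudes in mm at the distal
    #: reference radius; both enter the closed-form truth exactly.
    ellipticity_mm: float = 1.2
    crest_mm: float = 0.8
    angular_resolution: int = 64
    axial_resolution: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bone_radius < self.skin_radius_distal <= self.skin_radius_proximal:
            raise PhantomError(
                "require bone_radius < skin_radius_distal <= skin_radius_proximal, "
                f"got {self.bone_radius}, {self.skin_radius_distal}, "
                f"{self.skin_radius_proximal}"
            )
        if self.angular_resolution < 8 or self.axial_resolution < 8:
            raise PhantomError("angular/axial resolution must be >= 8")
        if not 0 <= self.bone_distal_z < self.bone_proximal_z:
            raise PhantomError("require 0 <= bone_distal_z < bone_proximal_z")
        if self.bone_proximal_z + self.bone_radius > self.limb_length:
            raise PhantomError("bone extends beyond the proximal end of the limb")


@dataclass(frozen=True)
class GaussianPatch:
    """A localized radial indentation (mm inward; negative = relief).

    Gaussian in the (axial, circumferential-arc) surface coordinates with
    isotropic standard deviation ``sd_mm``. ``axisymmetric`` patches
    depend on axial position only (a full circumferential band, used for
    the distal cup).
    """

    axial_mm: float
    angular_rad: float
    amplitude_mm: float
    sd_mm: float
    axisymmetric: bool = False
    name: str = ""


@dataclass(frozen=True)
class DeformationSpec:
    """An interface condition as a radial skin-displacement field."""

    mode: str = "custom"
    uniform_radial: float = 0.0
    patches: tuple[GaussianPatch, ...] = ()
    seed: int = 0

    @classmethod
    def hands_off(cls) -> "DeformationSpec":
        """Pressure-cast condition: near-uniform 2 mm radial compression."""
        return cls(mode="hands_off", uniform_radial=2.0)

    @classmethod
    def hands_on(cls) -> "DeformationSpec":
        """Rectified PTB condition: firmer overall fit plus classic features.

        A patellar-bar indentation and two supracondylar depressions
        (amplitudes in the 4-6 mm rectification range, sd ~10 mm — a
        patellar-tendon bar is a few centimetres across) near the
        proximal brim of the kept region, plus a total-contact distal
        cup: rectified sockets load the distal tissue evenly, so the cup
        is centred at the distal pole and scaled to take up most of the
        distal clearance excess left by the bone tip. Overall uniform
        compression is set above the hands-off level: rectification
        removes more cast volume, inducing deformation in a larger
        tissue volume.
        """
        return cls(
            mode="hands_on",
            uniform_radial=3.0,
            patches=(
                GaussianPatch(35.0, 0.0, 5.0, 10.0, name="patellar_bar"),
                GaussianPatch(40.0, 2.0, 4.5, 10.0, name="supracondylar_medial"),
                GaussianPatch(40.0, -2.0, 4.5, 10.0, name="supracondylar_lateral"),
                GaussianPatch(-40.0, 0.0, 8.0, 20.0, axisymmetric=True, name="distal_cup"),
            ),
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form geometry of the generated phantom."""

    spec: PhantomSpec

    def section_modulation(self, theta) -> np.ndarray:
        """Fractional angular modulation m(θ) of the cross-section radius."""
        s = self.spec
        theta = np.asarray(theta, dtype=np.float64)
        return (
            s.ellipticity_mm * np.cos(2.0 * (theta - 0.4))
            + s.crest_mm * np.cos(3.0 * (theta + 1.1))
        ) / s.skin_radius_distal

    def skin_radius(self, z, theta=None) -> np.ndarray:
        """Radius of the undeformed skin envelope at (z, θ) (mm).

        With ``theta`` omitted, returns the axisymmetric mean profile.
        """
        z = np.asarray(z, dtype=np.float64)
        s = self.spec
        shaft = s.skin_radius_distal + (
            s.skin_radius_proximal - s.skin_radius_distal
        ) * np.clip(z, 0.0, s.limb_length) / s.limb_length
        cap = np.sqrt(np.maximum(s.skin_radius_distal**2 - np.minimum(z, 0.0) ** 2, 0.0))
        base = np.where(z < 0, cap, shaft)
        if theta is None:
            return base
        return base * (1.0 + self.section_modulation(theta))

    def clearance(self, z, theta=None) -> np.ndarray:
        """Radial bone-to-skin clearance in the bone shaft region (mm)."""
        return self.skin_radius(z, theta) - self.spec.bone_radius

    def mid_shaft_range(self, margin: float = 15.0) -> tuple[float, float]:
        """Axial interval safely inside the cylindrical bone shaft."""
        return (self.spec.bone_distal_z + margin, self.spec.bone_proximal_z - margin)

    def clearance_table(self, n: int = 50) -> pd.DataFrame:
        z = np.linspace(self.spec.bone_distal_z, self.spec.bone_proximal_z, n)
        return pd.DataFrame(
            {"z_mm": z, "skin_radius_mm": self.skin_radius(z), "clearance_mm": self.clearance(z)}
        )


# ---------------------------------------------------------------------------
# surface-of-revolution mesh builder


def _revolve(rings: Sequence[tuple[float, float]], n_theta: int, name: str) -> TriangleMesh:
    """Triangulate a surface of revolution about z from (z, r) rings.

    Rings are ordered distal to proximal; a ring with r == 0 is a pole
    vertex. Winding is chosen so implied normals point outward.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    vertices: list[np.ndarray] = []
    ring_start: list[int] = []  # start index, or -1 significance via is_pole
    is_pole: list[bool] = []
    for z, r in rings:
        ring_start.append(len(vertices))
        if r == 0.0:
            vertices.append(np.array([0.0, 0.0, z]))
            is_pole.append(True)
        else:
            vertices.extend(np.column_stack([r * cos_t, r * sin_t, np.full(n_theta, z)]))
            is_pole.append(False)
    faces: list[tuple[int, int, int]] = []
    nxt = lambda i: (i + 1) % n_theta
    for k in range(len(rings) - 1):
        a, b = ring_start[k], ring_start[k + 1]
        if is_pole[k] and not is_pole[k + 1]:
            for i in range(n_theta):  # distal pole fan
                faces.append((b + nxt(i), b + i, a))
        elif not is_pole[k] and is_pole[k + 1]:
            for i in range(n_theta):  # proximal pole fan
                faces.append((a + i, a + nxt(i), b))
        elif not is_pole[k] and not is_pole[k + 1]:
            for i in range(n_theta):
                faces.append((a + i, a + nxt(i), b + i))
                faces.append((a + nxt(i), b + nxt(i), b + i))
        else:
            raise PhantomError("two consecutive pole rings")
    return TriangleMesh(np.array(vertices), np.array(faces), name)


def _capsule_rings(
    z_lo: float, z_hi: float, radius: float, n_cap: int, n_shaft: int
) -> list[tuple[float, float]]:
    """Rings of a z-aligned capsule: hemisphere, shaft, hemisphere."""
    rings: list[tuple[float, float]] = [(z_lo - radius, 0.0)]
    for k in range(1, n_cap + 1):
        phi = 0.5 * np.pi * k / n_cap
        rings.append((z_lo - radius * np.cos(phi), radius * np.sin(phi)))
    for j in range(1, n_shaft + 1):
        rings.append((z_lo + (z_hi - z_lo) * j / n_shaft, radius))
    for k in range(1, n_cap + 1):
        psi = 0.5 * np.pi * k / n_cap
        rings.append((z_hi + radius * np.sin(psi), radius * np.cos(psi)))
    rings.append((z_hi + radius, 0.0))
    # snap float-noise radii (cos(pi/2) ~ 6e-17) to exact poles, then drop
    # the duplicate rings created at hemisphere equators/poles
    rings = [(z, 0.0 if r < 1e-9 * radius else r) for z, r in rings]
    dedup = [rings[0]]
    for ring in rings[1:]:
        if not (abs(ring[0] - dedup[-1][0]) < 1e-12 and abs(ring[1] - dedup[-1][1]) < 1e-12):
            dedup.append(ring)
    return dedup


def generate_phantom_limb(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[TriangleMesh, TriangleMesh, PhantomTruth]:
    """Build the (hard-tissue, skin) phantom pair with its analytic truth.

    Both meshes are watertight and outward-oriented; generation is fully
    deterministic for a given spec.
    """
    truth = PhantomTruth(spec)
    n_theta = spec.angular_resolution
    n_cap = max(4, spec.axial_resolution // 3)

    # skin: distal hemisphere (pole at -Rd), tapered shaft, flat top disk
    rings: list[tuple[float, float]] = [(-spec.skin_radius_distal, 0.0)]
    for k in range(1, n_cap + 1):
        phi = 0.5 * np.pi * k / n_cap
        rings.append(
            (-spec.skin_radius_distal * np.cos(phi), spec.skin_radius_distal * np.sin(phi))
        )
    for j in range(1, spec.axial_resolution + 1):
        z = spec.limb_length * j / spec.axial_resolution
        rings.append((z, float(truth.skin_radius(z))))
    rings.append((spec.limb_length, 0.0))  # flat proximal cap (fan)
    skin = _revolve(rings, n_theta, "skin")
    # non-circular cross-section: scale xy by the angular modulation
    theta = np.arctan2(skin.vertices[:, 1], skin.vertices[:, 0])
    scale = 1.0 + truth.section_modulation(theta)
    skin.vertices[:, :2] *= scale[:, None]

    bone = _revolve(
        _capsule_rings(
            spec.bone_distal_z,
            spec.bone_proximal_z,
            spec.bone_radius,
            n_cap,
            max(8, spec.axial_resolution),
        ),
        n_theta,
        "hard_tissue",
    )
    return bone, skin, truth


def generate_multibone_hard_tissue(spec: PhantomSpec = PhantomSpec()) -> list[TriangleMesh]:
    """A multi-part hard-tissue set (tibia + fibula + patella analogues).

    For compile/merge testing: a main capsule ("tibia"), a thin offset
    capsule ("fibula") and a small sphere ("patella"), all inside the
    default skin envelope. No closed-form clearance is claimed.
    """
    n_theta = spec.angular_resolution
    n_cap = max(4, spec.axial_resolution // 3)
    tibia = _revolve(
        _capsule_rings(spec.bone_distal_z, spec.bone_proximal_z, spec.bone_radius, n_cap, 16),
        n_theta, "tibia",
    )
    fibula = _revolve(
        _capsule_rings(spec.bone_distal_z + 25.0, spec.bone_proximal_z, 5.0, n_cap, 16),
        max(16, n_theta // 2), "fibula",
    )
    fibula = TriangleMesh(fibula.vertices + np.array([24.0, 0.0, 0.0]), fibula.faces, "fibula")
    patella = _revolve(_capsule_rings(0.0, 1.0, 8.0, n_cap, 2), max(16, n_theta // 2), "patella")
    patella = TriangleMesh(
        patella.vertices + np.array([0.0, 22.0, spec.bone_proximal_z - 20.0]),
        patella.faces, "patella",
    )
    return [tibia, fibula, patella]


# ---------------------------------------------------------------------------
# deformation


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _displacement_field(skin: TriangleMesh, d: DeformationSpec) -> np.ndarray:
    v = skin.vertices
    z = v[:, 2]
    r_xy = np.hypot(v[:, 0], v[:, 1])
    theta = np.arctan2(v[:, 1], v[:, 0])
    u = np.full(len(v), float(d.uniform_radial))
    for p in d.patches:
        dz = z - p.axial_mm
        if p.axisymmetric:
            g = np.exp(-(dz**2) / (2.0 * p.sd_mm**2))
        else:
            arc = r_xy * np.abs(_wrap_angle(theta - p.angular_rad))
            g = np.exp(-(dz**2 + arc**2) / (2.0 * p.sd_mm**2))
        u += p.amplitude_mm * g
    return u


def _patch_blame(skin_vertex: np.ndarray, d: DeformationSpec) -> str:
    """Name of the patch contributing most at a vertex (for error messages)."""
    if not d.patches:
        return "uniform_radial"
    single = TriangleMesh(skin_vertex.reshape(1, 3), np.empty((0, 3), dtype=int))
    contrib = [
        abs(
            _displacement_field(
                single, DeformationSpec(uniform_radial=0.0, patches=(p,))
            )[0]
        )
        for p in d.patches
    ]
    best = int(np.argmax(contrib))
    return d.patches[best].name or f"patch_{best}"


def apply_socket_deformation(
    skin: TriangleMesh,
    d: DeformationSpec,
    truth: PhantomTruth | None = None,
) -> tuple[TriangleMesh, np.ndarray]:
    """Deform the skin radially inward and return the exact displacement.

    Each vertex moves inward along its local radial direction (cylindrical
    for the shaft and top, spherical from the cap centre for the distal
    cap) by ``uniform_radial`` plus the Gaussian patch contributions at
    its (axial, angular) position. Returns (deformed skin, per-vertex
    signed displacement in mm, positive inward). When ``truth`` is given,
    the deformed skin is checked for bone intersection.
    """
    v = skin.vertices
    z = v[:, 2]
    r_xy = np.hypot(v[:, 0], v[:, 1])
    u = _displacement_field(skin, d)

    direction = np.zeros_like(v)
    cap = z < 0
    norms = np.linalg.norm(v[cap], axis=1)
    direction[cap] = v[cap] / np.where(norms > 1e-12, norms, 1.0)[:, None]
    shaft = ~cap & (r_xy > 1e-12)
    direction[shaft, 0] = v[shaft, 0] / r_xy[shaft]
    direction[shaft, 1] = v[shaft, 1] / r_xy[shaft]
    movable = np.linalg.norm(direction, axis=1) > 0.5
    u_eff = np.where(movable, u, 0.0)

    deformed = TriangleMesh(
        v - u_eff[:, None] * direction, skin.faces.copy(), f"{skin.name}_{d.mode}"
    )

    if truth is not None:
        s = truth.spec
        dz_axis = np.clip(deformed.vertices[:, 2], s.bone_distal_z, s.bone_proximal_z)
        r_def = np.hypot(deformed.vertices[:, 0], deformed.vertices[:, 1])
        dist_axis = np.sqrt(r_def**2 + (deformed.vertices[:, 2] - dz_axis) ** 2)
        clearance = dist_axis - s.bone_radius
        if clearance.min() <= 0:
            i = int(np.argmin(clearance))
            raise PhantomError(
                f"deformation drives skin into bone at vertex {i} "
                f"(clearance {clearance.min():.3f} mm); dominant contribution: "
                f"{_patch_blame(v[i], d)}"
            )
    return deformed, u_eff


def apply_rigid_perturbation(
    mesh: TriangleMesh,
    max_angle_deg: float,
    max_translation_mm: float,
    seed: int = 0,
) -> tuple[TriangleMesh, RigidTransform]:
    """Seeded random rigid motion (rotation about the centroid) plus translation.

    Returns the perturbed mesh and the exact applied transform, for
    registration-recovery tests. Zero bounds give the identity.
    """
    if max_angle_deg < 0 or max_translation_mm < 0:
        raise ValueError("perturbation bounds must be non-negative")
    rng = np.random.default_rng(seed)
    if max_angle_deg == 0 and max_translation_mm == 0:
        t = RigidTransform.identity()
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(), mesh.name), t

    def _unit(r):
        vec = r.normal(size=3)
        return vec / np.linalg.norm(vec)

    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    axis = _unit(rng)
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(angle * axis).as_matrix()
    translation = rng.uniform(0.0, max_translation_mm) * _unit(rng)
    c = mesh.vertices.mean(axis=0)
    t = RigidTransform(R, c - R @ c + translation)
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.name), t


def phantom_landmarks(
    mesh: TriangleMesh,
    n: int = 10,
    transform: RigidTransform | None = None,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    distal_direction=(0.0, 0.0, -1.0),
) -> LandmarkPairs:
    """Well-spread landmark pairs on a bone and its transformed copy.

    Picks ``n`` vertices by farthest-point sampling seeded at the most
    distal vertex (spread picks at extremities and around the surface,
    as a careful manual selection would), pairs them with the same
    vertices mapped through ``transform``, and optionally adds Gaussian
    jitter of ``jitter_sigma`` mm to the target points to mimic manual
    selection error.
    """
    if n > mesh.n_vertices:
        raise ValueError(f"n={n} exceeds vertex count {mesh.n_vertices}")
    if n < 3:
        raise ValueError("need at least 3 landmarks")
    start = extreme_point(mesh, distal_direction).index
    selected = [start]
    d_min = np.linalg.norm(mesh.vertices - mesh.vertices[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d_min))
        selected.append(nxt)
        d_min = np.minimum(
            d_min, np.linalg.norm(mesh.vertices - mesh.vertices[nxt], axis=1)
        )
    src = mesh.vertices[selected]
    t = transform if transform is not None else RigidTransform.identity()
    dst = t.apply(src)
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        dst = dst + rng.normal(scale=jitter_sigma, size=dst.shape)
    return LandmarkPairs(src, dst)


def export_phantom_set(
    out_dir: str | Path,
    spec: PhantomSpec = PhantomSpec(),
    deformations: dict[str, DeformationSpec] | None = None,
) -> dict[str, Path]:
    """Write the standard phantom fixture set: STLs, truth CSVs, spec JSON.

    Default deformations are the two interface presets; files are
    byte-deterministic for a given spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if deformations is None:
        deformations = {
            "hands_on": DeformationSpec.hands_on(),
            "hands_off": DeformationSpec.hands_off(),
        }
    bone, skin, truth = generate_phantom_limb(spec)
    paths: dict[str, Path] = {}
    paths["hard_tissue"] = lio.write_stl(bone, out_dir / "hard_tissue.stl")
    paths["skin"] = lio.write_stl(skin, out_dir / "skin.stl")
    truth.clearance_table().to_csv(out_dir / "clearance_truth.csv", index=False)
    paths["clearance_truth"] = out_dir / "clearance_truth.csv"
    for cname, dspec in deformations.items():
        deformed, disp = apply_socket_deformation(skin, dspec, truth)
        paths[f"skin_{cname}"] = lio.write_stl(deformed, out_dir / f"skin_{cname}.stl")
        pd.DataFrame({"displacement_mm": disp}).to_csv(
            out_dir / f"displacement_{cname}.csv", index=False
        )
        paths[f"displacement_{cname}"] = out_dir / f"displacement_{cname}.csv"
    meta = {
        "phantom_spec": asdict(spec),
        "deformations": {k: asdict(v) for k, v in deformations.items()},
    }
    (out_dir / "phantom_spec.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["spec"] = out_dir / "phantom_spec.json"
    return paths
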