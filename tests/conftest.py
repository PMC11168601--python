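import numpy as np
import pytest

from limbmorph import PhantomSpec, TriangleMesh, generate_phantom_limb


def open_cylinder(radius: float, height: float, n_theta: int = 32, n_z: int = 10,
                  name: str = "cylinder") -> TriangleMesh:
    """Open-ended cylinder along z from 0 to height, outward-oriented."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rings = []
    for j in range(n_z + 1):
        z = height * j / n_z
        rings.append(np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.full(n_theta, z)]
        ))
    vertices = np.vstack(rings)
    faces = []
    for j in range(n_z):
        a, b = j * n_theta, (j + 1) * n_theta
        for i in range(n_theta):
            k = (i + 1) % n_theta
            faces.append((a + i, a + k, b + i))
            faces.append((a + k, b + k, b + i))
    return TriangleMesh(vertices, np.array(faces), name)


def fan_cube() -> TriangleMesh:
    """Unit cube with each face split into a symmetric 4-triangle fan.

    Every corner then touches equal triangle area on each incident face,
    so area-weighted corner normals are exactly (+-1,+-1,+-1)/sqrt(3).
    """
    corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                       dtype=float)
    quads = [  # CCW seen from outside
        (0, 1, 3, 2), (4, 6, 7, 5), (0, 4, 5, 1),
        (2, 3, 7, 6), (0, 2, 6, 4), (1, 5, 7, 3),
    ]
    vertices = list(corners)
    faces = []
    for q in quads:
        c = corners[list(q)].mean(axis=0)
        ci = len(vertices)
        vertices.append(c)
        for i in range(4):
            faces.append((q[i], q[(i + 1) % 4], ci))
    return TriangleMesh(np.array(vertices), np.array(faces), "fan_cube")


@pytest.fixture(scope="session")
def phantom_default():
    """Default-spec phantom: (hard tissue, skin, truth)."""
    return generate_phantom_limb(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_small():
    """Low-resolution phantom for oracle-scale tests (< 500 vertices each)."""
    return generate_phantom_limb(PhantomSpec(angular_resolution=16, axial_resolution=12))
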