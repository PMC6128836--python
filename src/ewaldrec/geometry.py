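"""Orientations, rotation matrices and point-group symmetry.

Conventions
-----------
Euler angles (phi, theta, psi) are intrinsic ZYZ, in degrees, matching the
(rot, tilt, psi) triplet used in common single-particle metadata.  The
object-to-lab rotation is

    A(phi, theta, psi) = Rz(psi) @ Ry(theta) @ Rz(phi)

so that a point with object-frame coordinates r appears in the image/lab
frame at A @ r, and projection is along the lab z axis.  The lab z axis
points from the detector toward the electron source; a slab of the specimen
at height z (Angstrom) above the particle centre is imaged at defocus
``defocus + z`` (underfocus positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Orientation",
    "rotation_matrix",
    "random_orientations",
    "SymmetryGroup",
]


def _wrap180(a: float) -> float:
    """Wrap an angle in degrees to [-180, 180)."""
    return float((a + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class Orientation:
    """Particle orientation as intrinsic ZYZ Euler angles in degrees."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self):
        object.__setattr__(self, "phi", _wrap180(self.phi))
        object.__setattr__(self, "psi", _wrap180(self.psi))
        th = float(self.theta)
        if not (-1e-9 <= th <= 180.0 + 1e-9):
            raise ValueError(f"theta must lie in [0, 180] degrees, got {th}")
        object.__setattr__(self, "theta", min(max(th, 0.0), 180.0))


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(o: Orientation) -> np.ndarray:
    """Object-to-lab rotation A = Rz(psi) @ Ry(theta) @ Rz(phi)."""
    return _rz(o.psi) @ _ry(o.theta) @ _rz(o.phi)


def random_orientations(n: int, rng: np.random.Generator) -> list[Orientation]:
    """Draw n orientations uniformly over SO(3) (quaternion sampling)."""
    from scipy.spatial.transform import Rotation

    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    rots = Rotation.from_quat(q)
    # intrinsic ZYZ: matrix = Rz(a) Ry(b) Rz(c) with (a, b, c) = (psi, theta, phi)
    eul = rots.as_euler("ZYZ", degrees=True)
    return [Orientation(phi=c, theta=b, psi=a) for a, b, c in eul]


def _axis_angle(axis, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.deg2rad(deg) * axis).as_matrix()


def _orthonormalize(m: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(m)
    return u @ vt


def _find_rotation(elems: list[np.ndarray], m: np.ndarray, atol: float = 1e-6) -> bool:
    return any(np.abs(m - e).max() < atol for e in elems)


def _close_group(generators: list[np.ndarray], max_order: int = 240) -> list[np.ndarray]:
    """Close a set of proper rotations under multiplication (BFS)."""
    elems: list[np.ndarray] = []
    frontier = [np.eye(3)] + [np.asarray(g) for g in generators]
    while frontier:
        g = _orthonormalize(frontier.pop())
        if _find_rotation(elems, g):
            continue
        elems.append(g)
        for e in list(elems):
            frontier.append(e @ g)
            frontier.append(g @ e)
        if len(elems) > max_order:
            raise RuntimeError("symmetry group failed to close")
    return elems


_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


class SymmetryGroup:
    """A closed set of proper rotations: C1, Cn (n-fold about z) or I.

    The icosahedral set uses the I2 convention (2-fold axes along x, y, z;
    5-fold axes along the icosahedron vertices (0, ±1, ±phi) and cyclic
    permutations), generated programmatically and verified closed with 60
    elements.
    """

    def __init__(self, name: str):
        name = name.strip()
        self.name = name
        upper = name.upper()
        if upper == "C1":
            self.rotations = [np.eye(3)]
        elif upper.startswith("C") and upper[1:].isdigit():
            n = int(upper[1:])
            if n < 1:
                raise ValueError(f"invalid cyclic symmetry {name!r}")
            self.rotations = [_rz(360.0 * k / n) for k in range(n)]
        elif upper == "I":
            gens = [
                _axis_angle([0.0, 0.0, 1.0], 180.0),
                _axis_angle([1.0, 0.0, 0.0], 180.0),
                _axis_angle([0.0, 1.0, _GOLDEN], 72.0),
            ]
            self.rotations = _close_group(gens)
            if len(self.rotations) != 60:
                raise RuntimeError(
                    f"icosahedral group closure produced {len(self.rotations)} elements"
                )
        else:
            raise ValueError(f"unknown symmetry group {name!r}")

    @property
    def order(self) -> int:
        return len(self.rotations)

    def __len__(self) -> int:
        return len(self.rotations)

    def __repr__(self) -> str:
        return f"SymmetryGroup({self.name!r}, order={self.order})"
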