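"""Residue-pair geometry: local frames, virtual C-beta atoms, Euler angles.

Every residue gets an orthonormal right-handed frame anchored at its C-beta
atom, with the z-axis pointing from C-alpha toward C-beta (the side-chain
direction) and the x-axis obtained by Gram-Schmidt of the N - CA bond vector
against the z-axis.  The relative placement of two such frames is encoded by
six coordinates {r, theta, phi, alpha, beta, gamma}: the inter-frame distance,
the polar angles of frame 2's origin seen from frame 1, and the z-y-z Euler
angles of the rotation carrying frame 1's axes onto frame 2's.  These six
numbers fully determine frame 2 given frame 1 and are invariant under rigid
motion of the pair, which makes them the natural arguments of an
orientation-dependent pair score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocalFrame",
    "RelativeCoordinates",
    "DegenerateGeometryError",
    "place_virtual_cbeta",
    "residue_frame",
    "euler_from_rotation",
    "rotation_from_euler",
    "relative_coordinates",
    "reconstruct_frame",
]

#: Ideal tetrahedral central angle, arccos(-1/3), in radians.
TETRAHEDRAL_ANGLE = math.acos(-1.0 / 3.0)

#: Canonical C-alpha -> C-beta bond length in Angstrom.
CA_CB_BOND_LENGTH = 1.53


class DegenerateGeometryError(ValueError):
    """Raised when backbone atoms are arranged so that a frame is undefined."""


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal right-handed frame anchored at a residue's C-beta atom."""

    origin: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    u_z: np.ndarray

    @property
    def axes(self) -> np.ndarray:
        """Axes as rows of a 3x3 matrix (world components)."""
        return np.vstack([self.u_x, self.u_y, self.u_z])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LocalFrame":
        """Frame after the rigid motion x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return LocalFrame(
            origin=rotation @ self.origin + translation,
            u_x=rotation @ self.u_x,
            u_y=rotation @ self.u_y,
            u_z=rotation @ self.u_z,
        )


@dataclass(frozen=True)
class RelativeCoordinates:
    """The six relative degrees of freedom between two residue frames.

    r       -- distance between the frame origins (C-beta separation), Angstrom
    theta   -- polar angle of frame 2's origin in frame 1, [0, pi]
    phi     -- azimuthal angle of frame 2's origin in frame 1, (-pi, pi]
    alpha, beta, gamma -- z-y-z Euler angles of the frame-1 -> frame-2
                          rotation; beta in [0, pi], alpha and gamma in
                          (-pi, pi]
    """

    r: float
    theta: float
    phi: float
    alpha: float
    beta: float
    gamma: float

    def as_vector(self, dim: int = 6) -> np.ndarray:
        """Project onto the 1D (r), 3D (r, theta, phi) or full 6D coordinates."""
        if dim == 1:
            return np.array([self.r])
        if dim == 3:
            return np.array([self.r, self.theta, self.phi])
        if dim == 6:
            return np.array(
                [self.r, self.theta, self.phi, self.alpha, self.beta, self.gamma]
            )
        raise ValueError(f"dim must be 1, 3 or 6, got {dim}")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError(f"zero-length vector for {what}")
    return v / n


def place_virtual_cbeta(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Place an idealised C-beta atom from the three backbone atoms.

    The construction assumes ideal tetrahedral central angles about C-alpha
    (both N-CA-CB and C-CA-CB equal arccos(-1/3) = 109.471 deg) and a CA-CB
    bond length of 1.53 Angstrom, and picks the root on the side consistent
    with L-amino-acid chirality.  Used for glycine, which has no real C-beta.
    """
    N = np.asarray(N, dtype=float)
    CA = np.asarray(CA, dtype=float)
    C = np.asarray(C, dtype=float)
    n = _unit(N - CA, "N-CA bond")
    c = _unit(C - CA, "C-CA bond")
    cross = np.cross(n, c)
    if np.linalg.norm(cross) < 1e-6:
        raise DegenerateGeometryError("N, CA, C are collinear")
    bisector = _unit(n + c, "N-CA-C bisector")
    normal = _unit(cross, "N-CA-C plane normal")
    # Both central angles are equal by symmetry about the bisector plane; the
    # in-plane tilt delta solves  d . n = cos(tetrahedral).
    cos_target = math.cos(TETRAHEDRAL_ANGLE)
    cos_half = float(bisector @ n)
    cos_delta = -cos_target / cos_half
    if abs(cos_delta) > 1.0:
        raise DegenerateGeometryError(
            "N-CA-C angle incompatible with tetrahedral C-beta placement"
        )
    sin_delta = math.sqrt(1.0 - cos_delta * cos_delta)
    # +normal selects the L-amino-acid branch (verified against real residues).
    direction = -cos_delta * bisector + sin_delta * normal
    return CA + CA_CB_BOND_LENGTH * direction


def residue_frame(res) -> LocalFrame:
    """Local frame of a residue: origin at CB, z along CA->CB, x from N-CA.

    Accepts any object with ``N``, ``CA`` and ``CB`` 3-vector attributes
    (a :class:`bbscore.structure.BackboneResidue` in practice).
    """
    CA = np.asarray(res.CA, dtype=float)
    CB = np.asarray(res.CB, dtype=float)
    N = np.asarray(res.N, dtype=float)
    if np.linalg.norm(CB - CA) < 0.5:
        raise DegenerateGeometryError("CB too close to CA for a frame")
    u_z = _unit(CB - CA, "CA-CB axis")
    nca = N - CA
    x_raw = nca - (nca @ u_z) * u_z
    if np.linalg.norm(x_raw) < 1e-6:
        raise DegenerateGeometryError("N-CA bond parallel to frame z-axis")
    u_x = _unit(x_raw, "frame x-axis")
    u_y = np.cross(u_z, u_x)
    return LocalFrame(origin=CB, u_x=u_x, u_y=u_y, u_z=u_z)


def rotation_from_euler(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix Rz(alpha) Ry(beta) Rz(gamma) (z-y-z convention)."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    return np.array(
        [
            [ca * cb * cg - sa * sg, -ca * cb * sg - sa * cg, ca * sb],
            [sa * cb * cg + ca * sg, -sa * cb * sg + ca * cg, sa * sb],
            [-sb * cg, sb * sg, cb],
        ]
    )


def euler_from_rotation(M: np.ndarray, tol: float = 1e-6) -> tuple[float, float, float]:
    """z-y-z Euler angles (alpha, beta, gamma) of a proper rotation matrix.

    beta = arccos(M[2, 2]) lies in [0, pi].  At the gimbal singularities
    beta in {0, pi} the decomposition is not unique; gamma is set to 0 and
    the whole in-plane rotation absorbed into alpha.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.allclose(M @ M.T, np.eye(3), atol=tol) or abs(np.linalg.det(M) - 1.0) > tol:
        raise ValueError("matrix is not a proper rotation within tolerance")
    cb = float(np.clip(M[2, 2], -1.0, 1.0))
    beta = math.acos(cb)
    sb = math.sin(beta)
    if sb < 1e-9:
        # Gimbal: only alpha +/- gamma is determined; take gamma = 0.
        if cb > 0:
            alpha = math.atan2(M[1, 0], M[0, 0])
        else:
            alpha = math.atan2(-M[1, 0], -M[0, 0])
        return alpha, beta, 0.0
    alpha = math.atan2(M[1, 2], M[0, 2])
    gamma = math.atan2(M[2, 1], -M[2, 0])
    return alpha, beta, gamma


def relative_coordinates(f1: LocalFrame, f2: LocalFrame) -> RelativeCoordinates:
    """Six relative coordinates of frame 2 with respect to frame 1.

    (r, theta, phi) are the spherical coordinates of f2's origin in f1
    (theta from u_z, phi from u_x toward u_y, set to 0 at the poles) and
    (alpha, beta, gamma) the z-y-z Euler angles of the rotation M with
    M[i, j] = u2_i . u1_j.
    """
    v12 = f2.origin - f1.origin
    r = float(np.linalg.norm(v12))
    if r < 1e-6:
        raise DegenerateGeometryError("coincident frame origins: theta/phi undefined")
    x = float(v12 @ f1.u_x)
    y = float(v12 @ f1.u_y)
    z = float(v12 @ f1.u_z)
    theta = math.acos(max(-1.0, min(1.0, z / r)))
    if theta < 1e-9 or math.pi - theta < 1e-9:
        phi = 0.0
    else:
        phi = math.atan2(y, x)
    M = f2.axes @ f1.axes.T
    alpha, beta, gamma = euler_from_rotation(M, tol=1e-6)
    return RelativeCoordinates(r=r, theta=theta, phi=phi, alpha=alpha, beta=beta, gamma=gamma)


def invert_relative_coordinates(rc: RelativeCoordinates) -> RelativeCoordinates:
    """Relative coordinates of frame 1 as seen from frame 2.

    Computed by placing frame 1 at the identity, reconstructing frame 2 from
    the six coordinates and measuring the reverse relation.
    """
    identity = LocalFrame(
        origin=np.zeros(3),
        u_x=np.array([1.0, 0.0, 0.0]),
        u_y=np.array([0.0, 1.0, 0.0]),
        u_z=np.array([0.0, 0.0, 1.0]),
    )
    return relative_coordinates(reconstruct_frame(identity, rc), identity)


def reconstruct_frame(f1: LocalFrame, rc: RelativeCoordinates) -> LocalFrame:
    """Rebuild frame 2 from frame 1 and the six relative coordinates."""
    st, ct = math.sin(rc.theta), math.cos(rc.theta)
    sp, cp = math.sin(rc.phi), math.cos(rc.phi)
    direction = st * cp * f1.u_x + st * sp * f1.u_y + ct * f1.u_z
    origin = f1.origin + rc.r * direction
    M = rotation_from_euler(rc.alpha, rc.beta, rc.gamma)
    axes2 = M @ f1.axes
    return LocalFrame(origin=origin, u_x=axes2[0], u_y=axes2[1], u_z=axes2[2])
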