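"""Rotation algebra shared by the IMU and optical motion-capture pipelines.

Conventions
-----------
Body frame axes (right-handed): X = anterior, Y = medial-lateral pointing
left, Z = vertical up.  Plane angles and their signs:

* sagittal (flexion/extension): rotation about +Y, positive = forward flexion
* frontal (side bend): rotation about -X, positive = left side bend
* transverse (axial rotation): rotation about +Z, positive = left rotation

Euler sequences are *intrinsic* rotations, applied in the order named by the
tag.  Three decomposition orders are supported, one per cued movement family:

* ``FE_SB_AR`` - sagittal, frontal, transverse (flexion/extension tasks)
* ``SB_FE_AR`` - frontal, sagittal, transverse (side-bend tasks)
* ``AR_FE_SB`` - transverse, sagittal, frontal (axial-rotation tasks)

All angles crossing module boundaries are degrees; radians never leave this
module.  Quaternion scalar convention is (w, x, y, z).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateFrameError, InvalidInputError

ORDER_TAGS = ("FE_SB_AR", "SB_FE_AR", "AR_FE_SB")

# Intrinsic scipy axis sequence and per-slot sign for each order tag.  The
# frontal angle is a rotation about -X, hence the sign flip on its slot.
_ORDER_SEQ = {
    "FE_SB_AR": "YXZ",
    "SB_FE_AR": "XYZ",
    "AR_FE_SB": "ZYX",
}
_ORDER_SIGNS = {
    "FE_SB_AR": np.array([1.0, -1.0, 1.0]),
    "SB_FE_AR": np.array([-1.0, 1.0, 1.0]),
    "AR_FE_SB": np.array([1.0, 1.0, -1.0]),
}
# Plane names occupying the primary/secondary/tertiary slots of each order.
ORDER_PLANES = {
    "FE_SB_AR": ("sagittal", "frontal", "transverse"),
    "SB_FE_AR": ("frontal", "sagittal", "transverse"),
    "AR_FE_SB": ("transverse", "sagittal", "frontal"),
}

_GIMBAL_TOL_DEG = 1e-6
ROTATION_ATOL = 1e-9


def _check_order(order_tag: str) -> None:
    if order_tag not in _ORDER_SEQ:
        raise InvalidInputError(
            f"unknown Euler order tag {order_tag!r}; expected one of {ORDER_TAGS}"
        )


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion (w, x, y, z); renormalized on construction.

    q and -q represent the same rotation (double cover); equality of the
    represented rotation, not of components, is what downstream code relies on.
    """

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        v = np.array([self.w, self.x, self.y, self.z], dtype=float)
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("quaternion components must be finite")
        n = float(np.linalg.norm(v))
        if n < 1e-12:
            raise InvalidInputError("zero-norm quaternion has no orientation")
        v /= n
        object.__setattr__(self, "w", float(v[0]))
        object.__setattr__(self, "x", float(v[1]))
        object.__setattr__(self, "y", float(v[2]))
        object.__setattr__(self, "z", float(v[3]))

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])


@dataclass(frozen=True)
class EulerTriple:
    """Three plane angles in degrees under a named decomposition order.

    ``gimbal_flag`` marks triples whose secondary angle sits at the +-90 deg
    singularity, where the primary/tertiary split is not unique.
    """

    primary: float
    secondary: float
    tertiary: float
    order_tag: str
    gimbal_flag: bool = field(default=False)

    def __post_init__(self) -> None:
        _check_order(self.order_tag)
        for a in (self.primary, self.secondary, self.tertiary):
            if not np.isfinite(a) or not (-180.0 < a <= 180.0 + 1e-9):
                raise InvalidInputError(f"angle {a} outside (-180, 180] degrees")

    def as_array(self) -> np.ndarray:
        return np.array([self.primary, self.secondary, self.tertiary])

    @property
    def planes(self) -> tuple[str, str, str]:
        return ORDER_PLANES[self.order_tag]


# ---------------------------------------------------------------------------
# quaternion <-> matrix
# ---------------------------------------------------------------------------

def quat_to_matrix(q: UnitQuaternion | np.ndarray) -> np.ndarray:
    """3x3 rotation matrix (local -> global) from a unit quaternion."""
    if isinstance(q, UnitQuaternion):
        arr = q.as_array()
    else:
        arr = np.asarray(q, dtype=float)
        if arr.shape != (4,):
            raise InvalidInputError("quaternion must have 4 components (w,x,y,z)")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("quaternion components must be finite")
        n = np.linalg.norm(arr)
        if n < 1e-12:
            raise InvalidInputError("zero-norm quaternion has no orientation")
        arr = arr / n
    return Rotation.from_quat(arr, scalar_first=True).as_matrix()


def quats_to_matrices(qwxyz: np.ndarray) -> np.ndarray:
    """Vectorized quat->matrix for an (N, 4) array of (w,x,y,z) quaternions."""
    q = np.asarray(qwxyz, dtype=float)
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-12) or not np.all(np.isfinite(q)):
        raise InvalidInputError("stream contains zero-norm or non-finite quaternions")
    return Rotation.from_quat(q / norms[:, None], scalar_first=True).as_matrix()


def matrix_to_quat(R: np.ndarray) -> UnitQuaternion:
    w, x, y, z = Rotation.from_matrix(R).as_quat(scalar_first=True)
    return UnitQuaternion(w, x, y, z)


# ---------------------------------------------------------------------------
# Euler decomposition / composition
# ---------------------------------------------------------------------------

def euler_decompose_many(R: np.ndarray, order_tag: str) -> np.ndarray:
    """Angles (deg), shape (N, 3), slots = (primary, secondary, tertiary).

    At the +-90 deg singularity of the secondary angle the tertiary angle is
    set to zero and the full remaining rotation assigned to the primary slot
    (deterministic tie-break); a warning is emitted per call.
    """
    _check_order(order_tag)
    R = np.asarray(R, dtype=float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ang = Rotation.from_matrix(R).as_euler(_ORDER_SEQ[order_tag], degrees=True)
    if any("Gimbal lock" in str(c.message) for c in caught):
        warnings.warn(
            f"gimbal lock in order {order_tag}: tertiary angle set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.atleast_2d(ang) * _ORDER_SIGNS[order_tag]


def euler_decompose(R: np.ndarray, order_tag: str) -> EulerTriple:
    """Decompose one rotation matrix into an :class:`EulerTriple`."""
    ang = euler_decompose_many(np.asarray(R, dtype=float)[None, :, :], order_tag)[0]
    gimbal = (90.0 - abs(ang[1])) < _GIMBAL_TOL_DEG
    return EulerTriple(ang[0], ang[1], ang[2], order_tag, gimbal_flag=gimbal)


def euler_compose_many(angles_deg: np.ndarray, order_tag: str) -> np.ndarray:
    """Rotation matrices (N, 3, 3) from (N, 3) angle triples in degrees."""
    _check_order(order_tag)
    a = np.atleast_2d(np.asarray(angles_deg, dtype=float)) * _ORDER_SIGNS[order_tag]
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("Euler angles must be finite")
    return Rotation.from_euler(_ORDER_SEQ[order_tag], a, degrees=True).as_matrix()


def euler_compose(angles: EulerTriple | np.ndarray, order_tag: str | None = None) -> np.ndarray:
    if isinstance(angles, EulerTriple):
        order_tag = angles.order_tag
        arr = angles.as_array()
    else:
        if order_tag is None:
            raise InvalidInputError("order_tag required when composing a raw triple")
        arr = np.asarray(angles, dtype=float)
    return euler_compose_many(arr[None, :], order_tag)[0]


# ---------------------------------------------------------------------------
# matrix hygiene
# ---------------------------------------------------------------------------

def is_rotation(R: np.ndarray, atol: float = ROTATION_ATOL) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        return False
    return (
        np.allclose(R @ R.T, np.eye(3), atol=atol)
        and abs(np.linalg.det(R) - 1.0) <= atol
    )


def assert_rotation(R: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    if not is_rotation(R, atol=atol):
        raise InvalidInputError("matrix is not a proper rotation")
    return np.asarray(R, dtype=float)


def orthonormalize(M: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3), keeping column 0 fixed.

    Mirrors the double-cross-product construction used for body frames: the
    first column's direction is preserved exactly, the third is rebuilt from
    the first two by a cross product, and the second by a second cross
    product.  Raises :class:`DegenerateFrameError` on rank-deficient input.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or not np.all(np.isfinite(M)):
        raise InvalidInputError("expected a finite 3x3 matrix")
    c0, c1 = M[:, 0], M[:, 1]
    n0 = np.linalg.norm(c0)
    if n0 < 1e-12:
        raise DegenerateFrameError("first axis has zero length")
    a0 = c0 / n0
    a2 = np.cross(a0, c1)
    n2 = np.linalg.norm(a2)
    if n2 < 1e-9 * max(1.0, np.linalg.norm(c1)):
        raise DegenerateFrameError("axes are collinear; frame is rank-deficient")
    a2 /= n2
    a1 = np.cross(a2, a0)
    return np.column_stack([a0, a1, a2])


def chordal_mean_rotation(R: np.ndarray) -> np.ndarray:
    """Mean of rotations as projection of the elementwise mean onto SO(3)."""
    R = np.asarray(R, dtype=float)
    M = R.mean(axis=0) if R.ndim == 3 else R
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def geodesic_angle_deg(R1: np.ndarray, R2: np.ndarray) -> np.ndarray:
    """Rotation angle(s) in degrees between matrices (broadcasts over N)."""
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.ndim == 2:
        R1 = R1[None]
    if R2.ndim == 2:
        R2 = R2[None]
    tr = np.einsum("nji,nji->n", R1, R2) if R1.shape == R2.shape else None
    if tr is None:  # broadcast one against many
        if R1.shape[0] == 1:
            tr = np.einsum("ji,nji->n", R1[0], R2)
        else:
            tr = np.einsum("nji,ji->n", R1, R2[0])
    c = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    out = np.degrees(np.arccos(c))
    return out if out.size > 1 else float(out[0])
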