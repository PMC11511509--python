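"""Segment-pair kinematics: relative rotations in body coordinates.

For a pair of sensors (S1 = distal, S2 = proximal) the rotation from the S1
body frame to the S2 body frame is the four-factor product

    R_S1body->S2body = R_S2local->S2body . R_global->S2local
                       . R_S1local->global . R_S1body->S1local

The same product serves both measurement systems, each with its own local
frames and calibrations.  The resulting matrix sequence is normalized to the
participant's static posture (last frames of the trial) and decomposed into
Euler angles under the movement's decomposition order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MOVEMENT_ORDER
from .errors import InsufficientStaticError, InvalidInputError
from .frames import BodyCalibration
from .rotations import ORDER_PLANES, chordal_mean_rotation, euler_decompose_many


@dataclass(frozen=True)
class SegmentPair:
    """A named sensor pair; S1 = distal, S2 = proximal."""

    name: str
    distal: str
    proximal: str


@dataclass
class AnglePath:
    """Euler-angle time series (deg) for one segment pair.

    ``angles`` is (N, 3) with columns (primary, secondary, tertiary) in the
    slot order of ``order_tag``; ``planes`` names the plane occupying each
    slot.
    """

    segment: str
    system: str
    movement: str
    order_tag: str
    t: np.ndarray
    angles: np.ndarray

    @property
    def planes(self) -> tuple[str, str, str]:
        return ORDER_PLANES[self.order_tag]

    @property
    def primary(self) -> np.ndarray:
        return self.angles[:, 0]

    def to_frame(self, participant: str = "", trial: int = 0) -> pd.DataFrame:
        """Long-format export: one row per frame."""
        return pd.DataFrame(
            {
                "participant": participant,
                "trial": trial,
                "system": self.system,
                "segment": self.segment,
                "movement": self.movement,
                "order": self.order_tag,
                "t": self.t,
                "primary": self.angles[:, 0],
                "secondary": self.angles[:, 1],
                "tertiary": self.angles[:, 2],
            }
        )


def relative_rotation(
    R_s1_local_to_global: np.ndarray,
    R_s2_local_to_global: np.ndarray,
    cal1: BodyCalibration,
    cal2: BodyCalibration,
) -> np.ndarray:
    """Four-factor body-to-body rotation for a single frame."""
    R1 = np.asarray(R_s1_local_to_global, float)
    R2 = np.asarray(R_s2_local_to_global, float)
    return cal2.R_local_to_body @ R2.T @ R1 @ cal1.R_local_to_body.T


def relative_rotation_path(
    R1: np.ndarray, R2: np.ndarray, cal1: BodyCalibration, cal2: BodyCalibration
) -> np.ndarray:
    """Vectorized four-factor product over (N, 3, 3) streams."""
    R1 = np.asarray(R1, float)
    R2 = np.asarray(R2, float)
    if R1.shape != R2.shape or R1.ndim != 3:
        raise InvalidInputError("streams must be matched (N, 3, 3) arrays")
    A = cal2.R_local_to_body
    B = cal1.R_local_to_body.T
    # A @ R2^T @ R1 @ B per frame
    M = np.einsum("nji,njk->nik", R2, R1)  # R2^T R1
    return np.einsum("ij,njk,kl->nil", A, M, B)


def lowpass_rotations(R: np.ndarray, t: np.ndarray, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass of a rotation path via its rotation vectors.

    Standard conditioning of kinematic signals before peak extraction:
    measurement jitter well above the movement bandwidth is removed without
    phase distortion.  Valid for smooth paths away from the 180 deg
    rotation-vector discontinuity (trunk/hip angles stay far below it).
    """
    from scipy.signal import butter, sosfiltfilt
    from scipy.spatial.transform import Rotation

    R = np.asarray(R, float)
    if cutoff_hz <= 0 or R.shape[0] <= 24:
        return R
    fs = 1.0 / float(np.median(np.diff(np.asarray(t, float))))
    if cutoff_hz >= fs / 2:
        return R
    v = Rotation.from_matrix(R).as_rotvec()
    sos = butter(4, cutoff_hz / (fs / 2), output="sos")
    # pad with the local edge means so the filtered endpoints converge to the
    # local average rather than tracking a single noisy boundary sample
    # (reflective padding would bias the trailing static frames that the
    # normalization step relies on)
    k = max(2, int(round(0.25 * fs)))
    pad = int(round(2.0 * fs / cutoff_hz))
    head = np.tile(v[:k].mean(axis=0), (pad, 1))
    tail = np.tile(v[-k:].mean(axis=0), (pad, 1))
    ext = np.concatenate([head, v, tail], axis=0)
    out = sosfiltfilt(sos, ext, axis=0)[pad:-pad]
    return Rotation.from_rotvec(out).as_matrix()


def normalize_to_static(R_rel: np.ndarray, n_static: int = 5) -> np.ndarray:
    """Express a rotation sequence relative to its trailing static posture.

    The normalization matrix is the chordal mean of the last ``n_static``
    frames; every frame is right-multiplied by its inverse, so the static
    tail decomposes to angles near zero.
    """
    R_rel = np.asarray(R_rel, float)
    if R_rel.ndim != 3 or R_rel.shape[0] < n_static:
        raise InsufficientStaticError(
            f"trial has fewer than {n_static} frames for static normalization"
        )
    R0 = chordal_mean_rotation(R_rel[-n_static:])
    return np.einsum("nij,kj->nik", R_rel, R0)  # R_t @ R0^T


def angle_path(
    R_rel_normalized: np.ndarray,
    movement: str,
    t: np.ndarray,
    segment: str = "",
    system: str = "",
    lowpass_hz: float = 0.0,
) -> AnglePath:
    """Decompose a normalized rotation sequence under the movement's order.

    ``lowpass_hz`` > 0 applies a zero-phase 4th-order Butterworth to each
    angle trace - standard conditioning of kinematic signals so measurement
    jitter does not inflate the extracted peaks.
    """
    if movement not in MOVEMENT_ORDER:
        raise InvalidInputError(
            f"unknown movement label {movement!r}; expected one of {sorted(MOVEMENT_ORDER)}"
        )
    order = MOVEMENT_ORDER[movement]
    t = np.asarray(t, float)
    ang = euler_decompose_many(np.asarray(R_rel_normalized, float), order)
    if lowpass_hz > 0 and len(t) > 24:
        from scipy.signal import butter, sosfiltfilt

        fs = 1.0 / float(np.median(np.diff(t)))
        if lowpass_hz < fs / 2:
            sos = butter(4, lowpass_hz / (fs / 2), output="sos")
            ang = sosfiltfilt(sos, ang, axis=0)
    return AnglePath(
        segment=segment,
        system=system,
        movement=movement,
        order_tag=order,
        t=t,
        angles=ang,
    )
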