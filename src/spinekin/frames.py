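"""Sensor coordinate frames and functional 'body' calibration.

Both measurement systems deliver, per sensor, a time series of local->global
rotations: the IMU directly as quaternions from its on-board fusion, the
optical system via a rigid three-marker cluster on the sensor casing.  The
functional alignment procedure converts those arbitrary local frames into a
common anatomically meaningful 'body' frame:

* medial-lateral axis: principal rotation axis of one flexion repetition,
  oriented so flexion is a positive rotation (right-hand rule);
* vertical axis: gravity direction during a static standing pose (IMU: from
  orientation with respect to gravity; optical: the global-vertical column of
  the cluster orientation);
* anterior-posterior axis: cross product of the two, with a second cross
  product re-deriving the vertical so the frame is exactly orthonormal.

The calibration makes downstream joint angles invariant to how the sensor
happened to be mounted on the skin.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CalibrationTooSmallError,
    DegenerateFrameError,
    InvalidInputError,
    MissingDataError,
    MissingFrameError,
    NotStaticError,
)
from .rotations import (
    UnitQuaternion,
    chordal_mean_rotation,
    geodesic_angle_deg,
    quats_to_matrices,
)

GLOBAL_UP = np.array([0.0, 0.0, 1.0])  # global frame is Z-up


@dataclass(frozen=True)
class OrientationSample:
    """One timestamped local->global unit quaternion."""

    t: float
    q: UnitQuaternion


@dataclass(frozen=True)
class MarkerClusterFrame:
    """One timestamped triple of marker positions (mm, global frame)."""

    t: float
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    visible: tuple[bool, bool, bool] = (True, True, True)

    def points(self) -> np.ndarray:
        return np.stack([np.asarray(self.p1, float),
                         np.asarray(self.p2, float),
                         np.asarray(self.p3, float)])


@dataclass
class BodyCalibration:
    """Per sensor, per system: the local->body rotation from alignment."""

    sensor_id: str
    system: str  # "IMU" | "OMC"
    R_local_to_body: np.ndarray
    ml_axis_local: np.ndarray | None = None
    vertical_axis_local: np.ndarray | None = None
    R_static_ref: np.ndarray | None = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "sensor_id": self.sensor_id,
            "system": self.system,
            "R_local_to_body": np.asarray(self.R_local_to_body).tolist(),
        }
        if self.ml_axis_local is not None:
            d["ml_axis_local"] = np.asarray(self.ml_axis_local).tolist()
        if self.vertical_axis_local is not None:
            d["vertical_axis_local"] = np.asarray(self.vertical_axis_local).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BodyCalibration":
        return cls(
            sensor_id=d["sensor_id"],
            system=d["system"],
            R_local_to_body=np.asarray(d["R_local_to_body"], float),
            ml_axis_local=np.asarray(d["ml_axis_local"], float) if "ml_axis_local" in d else None,
            vertical_axis_local=(
                np.asarray(d["vertical_axis_local"], float) if "vertical_axis_local" in d else None
            ),
        )


def identity_calibration(sensor_id: str, system: str = "IMU") -> BodyCalibration:
    return BodyCalibration(sensor_id, system, np.eye(3))


# ---------------------------------------------------------------------------
# cluster orientation
# ---------------------------------------------------------------------------

def _cluster_matrix(points: np.ndarray) -> np.ndarray:
    """Right-handed frame from 3 markers: e1 along p2-p1, plane via p3-p1."""
    p1, p2, p3 = points
    v1 = p2 - p1
    v2 = p3 - p1
    n1 = np.linalg.norm(v1)
    if n1 < 1e-9:
        raise DegenerateFrameError("markers 1 and 2 coincide")
    e1 = v1 / n1
    e3 = np.cross(e1, v2)
    n3 = np.linalg.norm(e3)
    if n3 < 1e-6 * max(1.0, np.linalg.norm(v2)):
        raise DegenerateFrameError("markers are collinear; cluster frame undefined")
    e3 /= n3
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def omc_cluster_orientation(frame: MarkerClusterFrame) -> np.ndarray:
    """Local->global rotation of one rigid marker-cluster frame.

    Deterministic in marker label order (axis recipe: origin at marker 1,
    first axis along marker 2, marker 3 fixes the plane).
    """
    if not all(frame.visible):
        raise MissingFrameError(
            f"occluded marker(s) at t={frame.t}: visible={frame.visible}"
        )
    return _cluster_matrix(frame.points())


def cluster_orientations(points: np.ndarray, visible: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cluster orientation for (N, 3, 3) marker positions.

    Returns (R, valid) where R is (N, 3, 3) (NaN rows where invalid) and
    valid a boolean mask.  Occluded or collinear frames are masked, not
    raised, so callers can apply their own gap policy.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if visible is None:
        visible = np.all(np.isfinite(points), axis=(1, 2))
    else:
        visible = np.asarray(visible, bool).all(axis=1) & np.all(
            np.isfinite(points), axis=(1, 2)
        )
    v1 = points[:, 1] - points[:, 0]
    v2 = points[:, 2] - points[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = v1 / np.linalg.norm(v1, axis=1, keepdims=True)
        e3 = np.cross(e1, v2)
        n3 = np.linalg.norm(e3, axis=1, keepdims=True)
        e3 = e3 / n3
        e2 = np.cross(e3, e1)
    valid = visible & np.isfinite(e1).all(axis=1) & (n3[:, 0] > 1e-6)
    R = np.full((n, 3, 3), np.nan)
    R[valid] = np.stack([e1[valid], e2[valid], e3[valid]], axis=-1)
    return R, valid


# ---------------------------------------------------------------------------
# functional alignment
# ---------------------------------------------------------------------------

def _as_matrix_stream(stream) -> np.ndarray:
    if isinstance(stream, np.ndarray) and stream.ndim == 3:
        return stream
    if len(stream) and isinstance(stream[0], OrientationSample):
        return quats_to_matrices(np.stack([s.q.as_array() for s in stream]))
    return np.asarray(stream, dtype=float)


def functional_ml_axis(stream, min_excursion_deg: float = 15.0) -> np.ndarray:
    """Medial-lateral axis (unit vector, sensor-local) from a flexion repetition.

    Fits the principal axis of the relative angular displacement: rotation
    vectors of R_0^-1 R_t are accumulated into an outer-product matrix whose
    dominant eigenvector is the (local-frame) rotation axis.  The sign is
    oriented so the net rotation over the repetition is positive, making
    flexion a positive rotation about the returned axis.
    """
    from scipy.spatial.transform import Rotation

    R = _as_matrix_stream(stream)
    if R.ndim != 3 or R.shape[0] < 2:
        raise InvalidInputError("need a stream of at least 2 orientations")
    rel = np.einsum("ji,njk->nik", R[0], R)  # R_0^T R_t, axis fixed in local frame
    v = Rotation.from_matrix(rel).as_rotvec()
    mags = np.degrees(np.linalg.norm(v, axis=1))
    if mags.max() < min_excursion_deg:
        raise CalibrationTooSmallError(
            f"calibration excursion {mags.max():.1f} deg < {min_excursion_deg} deg"
        )
    M = v.T @ v
    w, vec = np.linalg.eigh(M)
    axis = vec[:, -1]
    proj = v @ axis
    if proj[np.argmax(np.abs(proj))] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _check_static(R: np.ndarray, max_excursion_deg: float) -> np.ndarray:
    """Verify a window is static and return its chordal-mean orientation.

    Slow motion (trend) is measured between chordal means of four
    sub-windows, so stationary zero-mean sensor jitter does not masquerade
    as movement; brief transients are caught separately by the raw per-frame
    excursion against a 3x threshold.  Very short windows use the raw
    excursion only.
    """
    mean = chordal_mean_rotation(R)
    n = R.shape[0]
    raw = float(np.max(np.atleast_1d(geodesic_angle_deg(mean, R))))
    if n >= 8:
        quarters = np.array_split(np.arange(n), 4)
        means = np.stack([chordal_mean_rotation(R[idx]) for idx in quarters])
        trend = max(
            geodesic_angle_deg(means[i], means[j])
            for i in range(4) for j in range(i + 1, 4)
        )
        static = trend <= max_excursion_deg and raw <= 3.0 * max_excursion_deg
        exc = max(trend, raw / 3.0)
    else:
        static = raw <= max_excursion_deg
        exc = raw
    if not static:
        raise NotStaticError(
            f"window excursion {exc:.2f} deg exceeds {max_excursion_deg} deg"
        )
    return mean


def vertical_axis_imu(static_stream, max_excursion_deg: float = 2.0) -> np.ndarray:
    """Gravity 'up' direction in sensor-local coordinates from a static pose."""
    R = _as_matrix_stream(static_stream)
    if R.ndim != 3 or R.shape[0] < 1:
        raise InvalidInputError("need at least one orientation sample")
    mean = _check_static(R, max_excursion_deg)
    v = mean.T @ GLOBAL_UP
    return v / np.linalg.norm(v)


def vertical_axis_omc(static_frames, max_excursion_deg: float = 2.0) -> np.ndarray:
    """As :func:`vertical_axis_imu`, sourced from marker-cluster orientations."""
    if isinstance(static_frames, np.ndarray) and static_frames.ndim == 3 and static_frames.shape[1:] == (3, 3):
        R, valid = static_frames, np.ones(static_frames.shape[0], bool)
        valid = np.isfinite(R).all(axis=(1, 2))
    else:
        frames = list(static_frames)
        points = np.stack([f.points() for f in frames])
        vis = np.array([f.visible for f in frames])
        R, valid = cluster_orientations(points, vis)
    if not valid.any():
        raise MissingDataError("all frames of the static window are occluded")
    mean = _check_static(R[valid], max_excursion_deg)
    v = mean.T @ GLOBAL_UP
    return v / np.linalg.norm(v)


def build_body_calibration(
    ml_axis: np.ndarray,
    vertical_axis: np.ndarray,
    sensor_id: str = "",
    system: str = "IMU",
    min_angle_deg: float = 10.0,
) -> BodyCalibration:
    """Double-cross-product body frame from the two calibration axes.

    The medial-lateral axis is kept exactly; the anterior-posterior axis is
    cross(ml, vertical) normalized; the vertical axis is re-derived by a
    second cross product so the frame is exactly orthonormal.  Body-frame
    column convention: X = anterior-posterior, Y = medial-lateral,
    Z = vertical.
    """
    ml = np.asarray(ml_axis, dtype=float)
    vt = np.asarray(vertical_axis, dtype=float)
    ml = ml / np.linalg.norm(ml)
    vt = vt / np.linalg.norm(vt)
    sep = np.degrees(np.arccos(np.clip(ml @ vt, -1.0, 1.0)))
    if min(sep, 180.0 - sep) < min_angle_deg:
        raise DegenerateFrameError(
            f"medial-lateral and vertical axes only {min(sep, 180 - sep):.1f} deg apart"
        )
    ap = np.cross(ml, vt)
    ap /= np.linalg.norm(ap)
    vt2 = np.cross(ap, ml)  # second cross product; unit by construction
    B = np.column_stack([ap, ml, vt2])  # body axes expressed in local coords
    return BodyCalibration(
        sensor_id=sensor_id,
        system=system,
        R_local_to_body=B.T,
        ml_axis_local=ml,
        vertical_axis_local=vt,
    )
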