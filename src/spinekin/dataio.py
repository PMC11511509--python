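"""File formats, stomp synchronization and timeline resampling.

Formats (all plain text):

* IMU CSV - package-defined dialect (the vendor app's format is unpublished):
  two ``#`` header lines declaring version and units, then columns
  ``t,qw,qx,qy,qz,ax,ay,az,gx,gy,gz,mx,my,mz`` with time in seconds,
  quaternions (w,x,y,z), acceleration m/s^2, angular velocity rad/s,
  magnetic field uT.
* TRC - the tab-separated marker trajectory format used by optical capture
  tooling; occluded frames are empty fields.  Positions are mm, Z-up.
* Marker CSV - a wide CSV fallback with ``<label>_x/_y/_z`` columns.

Writers and readers round-trip byte-identically (fixed numeric formats).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation, Slerp

from .errors import (
    AmbiguousSyncError,
    DataFormatError,
    InvalidInputError,
    SyncFailureError,
)

log = logging.getLogger(__name__)

IMU_HEADER = "# spinekin-imu-v1"
IMU_UNITS = "# units: t=s quat=unit(w,x,y,z) accel=m/s^2 gyro=rad/s mag=uT"
IMU_COLUMNS = ["t", "qw", "qx", "qy", "qz", "ax", "ay", "az",
               "gx", "gy", "gz", "mx", "my", "mz"]


@dataclass
class ImuStream:
    """One sensor's IMU record: orientation plus raw inertial channels."""

    t: np.ndarray  # seconds
    quat_wxyz: np.ndarray  # (N, 4) unit quaternions, local->global
    accel: np.ndarray  # (N, 3) m/s^2, sensor frame (specific force)
    gyro: np.ndarray  # (N, 3) rad/s, sensor frame
    mag: np.ndarray  # (N, 3) uT, sensor frame

    def rotations(self) -> np.ndarray:
        from .rotations import quats_to_matrices

        return quats_to_matrices(self.quat_wxyz)

    def shifted(self, offset_s: float) -> "ImuStream":
        return ImuStream(self.t - offset_s, self.quat_wxyz, self.accel,
                         self.gyro, self.mag)


@dataclass
class MarkerStream:
    """One sensor's rigid 3-marker cluster trajectory (mm, global frame)."""

    t: np.ndarray  # seconds
    points: np.ndarray  # (N, 3 markers, 3 coords), NaN where occluded
    visible: np.ndarray  # (N, 3) bool


# ---------------------------------------------------------------------------
# IMU CSV
# ---------------------------------------------------------------------------

def write_imu_csv(stream: ImuStream, path: str | Path) -> None:
    data = np.column_stack([stream.t, stream.quat_wxyz, stream.accel,
                            stream.gyro, stream.mag])
    lines = [IMU_HEADER, IMU_UNITS, ",".join(IMU_COLUMNS)]
    for row in data:
        lines.append(",".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_imu_csv(path: str | Path) -> ImuStream:
    """Read and validate one IMU stream.

    Non-unit quaternions are renormalized (count logged); malformed rows and
    timestamp regressions raise :class:`DataFormatError` with the line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:  # noqa: BLE001 - wrap any parse failure
        raise DataFormatError(f"{path}: cannot parse ({e})") from e
    if list(df.columns) != IMU_COLUMNS:
        raise DataFormatError(
            f"{path}: header mismatch; expected columns {IMU_COLUMNS}"
        )
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))
    if bad.size:
        raise DataFormatError(f"{path}: malformed row at line {bad[0] + 4}")
    t = arr[:, 0]
    if np.any(np.diff(t) <= 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise DataFormatError(f"{path}: timestamp regression at line {i + 5}")
    q = arr[:, 1:5]
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-12):
        raise DataFormatError(f"{path}: zero-norm quaternion present")
    off = np.abs(norms - 1.0) > 1e-6
    if off.any():
        log.warning("%s: renormalized %d non-unit quaternions", path, int(off.sum()))
        q = q / norms[:, None]
    return ImuStream(t=t, quat_wxyz=q, accel=arr[:, 5:8], gyro=arr[:, 8:11],
                     mag=arr[:, 11:14])


# ---------------------------------------------------------------------------
# marker files (TRC and wide CSV)
# ---------------------------------------------------------------------------

def _marker_table(streams: dict[str, MarkerStream],
                  marker_labels: dict) -> tuple[np.ndarray, list[str], np.ndarray]:
    sensors = list(streams)
    t = streams[sensors[0]].t
    labels, cols = [], []
    for s in sensors:
        if not np.array_equal(streams[s].t, t):
            raise InvalidInputError("marker streams must share one timeline")
        for m, lab in enumerate(marker_labels[s]):
            labels.append(lab)
            cols.append(streams[s].points[:, m, :])
    return t, labels, np.concatenate(cols, axis=1)  # (N, 3*n_markers)


def write_trc(streams: dict[str, MarkerStream], path: str | Path,
              marker_labels: dict, rate_hz: float = 120.0) -> None:
    t, labels, xyz = _marker_table(streams, marker_labels)
    n = len(t)
    head1 = f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}"
    head2 = ("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
             "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    head3 = (f"{rate_hz:g}\t{rate_hz:g}\t{n}\t{len(labels)}\tmm\t"
             f"{rate_hz:g}\t1\t{n}")
    head4 = "Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t"
    head5 = "\t\t" + "\t".join(
        f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels))
    )
    lines = [head1, head2, head3, head4, head5, ""]
    for i in range(n):
        vals = []
        for j in range(xyz.shape[1]):
            v = xyz[i, j]
            vals.append("" if not np.isfinite(v) else f"{v:.5f}")
        lines.append(f"{i+1}\t{t[i]:.6f}\t" + "\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def _streams_from_table(t: np.ndarray, labels: list[str], xyz: np.ndarray,
                        marker_labels: dict) -> dict[str, MarkerStream]:
    col = {lab: i for i, lab in enumerate(labels)}
    expected = [lab for labs in marker_labels.values() for lab in labs]
    unknown = [lab for lab in labels if lab not in expected]
    missing_sensors = [
        s for s, labs in marker_labels.items() if not all(l in col for l in labs)
    ]
    if unknown:
        raise DataFormatError(
            f"unknown marker labels {unknown}; expected {expected}"
        )
    out = {}
    for s, labs in marker_labels.items():
        if s in missing_sensors:
            continue
        pts = np.stack([xyz[:, 3 * col[l]:3 * col[l] + 3] for l in labs], axis=1)
        # zero-filled occlusion blocks (a common export convention) -> gaps
        zero = np.all(pts == 0.0, axis=2)
        pts[zero] = np.nan
        visible = np.isfinite(pts).all(axis=2)
        out[s] = MarkerStream(t=t, points=pts, visible=visible)
    return out


def read_trc(path: str | Path, marker_labels: dict) -> dict[str, MarkerStream]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise DataFormatError(f"{path}: not a TRC file")
    labels = [x for x in lines[3].split("\t")[2:] if x]
    n_cols = 2 + 3 * len(labels)
    rows_t, rows_xyz = [], []
    for ln, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split("\t")
        parts += [""] * (n_cols - len(parts))
        try:
            rows_t.append(float(parts[1]))
            rows_xyz.append([float(p) if p != "" else np.nan for p in parts[2:n_cols]])
        except ValueError as e:
            raise DataFormatError(f"{path}: malformed row at line {ln}") from e
    return _streams_from_table(np.array(rows_t), labels,
                               np.array(rows_xyz, dtype=float), marker_labels)


def write_markers_csv(streams: dict[str, MarkerStream], path: str | Path,
                      marker_labels: dict) -> None:
    t, labels, xyz = _marker_table(streams, marker_labels)
    cols = ["t"] + [f"{lab}_{ax}" for lab in labels for ax in "xyz"]
    lines = [",".join(cols)]
    for i in range(len(t)):
        vals = [f"{t[i]:.6f}"] + [
            "" if not np.isfinite(v) else f"{v:.5f}" for v in xyz[i]
        ]
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_markers_csv(path: str | Path, marker_labels: dict) -> dict[str, MarkerStream]:
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise DataFormatError(f"{path}: missing 't' column")
    labels = []
    for c in df.columns[1:]:
        if c.endswith("_x"):
            labels.append(c[:-2])
    xyz = np.column_stack([
        df[[f"{lab}_x", f"{lab}_y", f"{lab}_z"]].to_numpy(dtype=float)
        for lab in labels
    ])
    return _streams_from_table(df["t"].to_numpy(dtype=float), labels, xyz,
                               marker_labels)


def read_markers(path: str | Path, fmt: str | None = None,
                 marker_labels: dict | None = None) -> dict[str, MarkerStream]:
    """Read marker-cluster streams keyed by sensor; format by extension."""
    from .config import PipelineConfig

    marker_labels = marker_labels or PipelineConfig().marker_labels
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "trc":
        return read_trc(path, marker_labels)
    if fmt == "csv":
        return read_markers_csv(path, marker_labels)
    raise DataFormatError(f"unsupported marker format {fmt!r} (trc or csv)")


# ---------------------------------------------------------------------------
# synchronization and resampling
# ---------------------------------------------------------------------------

def _stomp_time(stream: ImuStream, min_height: float, ambiguity_ratio: float) -> float:
    a = np.linalg.norm(stream.accel, axis=1)
    dev = a - np.median(a)
    peaks, props = find_peaks(dev, height=min_height)
    if peaks.size == 0:
        raise SyncFailureError(
            f"no acceleration peak above {min_height} m/s^2; cannot synchronize"
        )
    heights = props["peak_heights"]
    best = peaks[np.argmax(heights)]
    t_best = stream.t[best]
    rivals = peaks[(heights >= ambiguity_ratio * heights.max())
                   & (np.abs(stream.t[peaks] - t_best) > 0.2)]
    if rivals.size:
        raise AmbiguousSyncError(
            "multiple comparable acceleration peaks; stomp is ambiguous"
        )
    return float(t_best)


def sync_imus(streams: dict[str, ImuStream], min_height: float = 25.0,
              ambiguity_ratio: float = 0.8) -> dict[str, float]:
    """Per-stream clock offsets from the shared stomp spike.

    Offsets are relative to the first stream; subtracting each offset from
    its stream's timestamps aligns the stomp peaks to within one sample
    period.
    """
    sensors = list(streams)
    times = {s: _stomp_time(streams[s], min_height, ambiguity_ratio)
             for s in sensors}
    ref = times[sensors[0]]
    return {s: times[s] - ref for s in sensors}


def resample_imu(stream: ImuStream, target_t: np.ndarray) -> ImuStream:
    """Resample onto a new timeline: orientation by spherical interpolation
    on the rotation manifold, vector channels linearly, endpoints clamped."""
    t = stream.t
    if np.any(np.diff(t) <= 0):
        raise DataFormatError("timestamps must be strictly increasing")
    tt = np.clip(np.asarray(target_t, float), t[0], t[-1])
    rot = Rotation.from_quat(stream.quat_wxyz, scalar_first=True)
    quat = Slerp(t, rot)(tt).as_quat(scalar_first=True)

    def lin(x):
        return np.column_stack([np.interp(tt, t, x[:, i]) for i in range(x.shape[1])])

    return ImuStream(t=np.asarray(target_t, float), quat_wxyz=quat,
                     accel=lin(stream.accel), gyro=lin(stream.gyro),
                     mag=lin(stream.mag))


def resample_markers(stream: MarkerStream, target_t: np.ndarray,
                     max_gap_s: float = 0.25) -> MarkerStream:
    """Linear position interpolation; occlusion gaps wider than ``max_gap_s``
    are preserved as gaps instead of being bridged."""
    t = stream.t
    tt = np.clip(np.asarray(target_t, float), t[0], t[-1])
    n = tt.size
    pts = np.full((n, 3, 3), np.nan)
    vis = np.zeros((n, 3), dtype=bool)
    for m in range(3):
        ok = stream.visible[:, m]
        if ok.sum() < 2:
            continue
        tv = t[ok]
        for c in range(3):
            pts[:, m, c] = np.interp(tt, tv, stream.points[ok, m, c])
        # locate wide gaps in the source and mask target samples inside them
        gap_mask = np.zeros(n, dtype=bool)
        dgaps = np.diff(tv)
        for i in np.flatnonzero(dgaps > max_gap_s):
            gap_mask |= (tt > tv[i]) & (tt < tv[i + 1])
        pts[gap_mask, m, :] = np.nan
        vis[:, m] = ~gap_mask
    return MarkerStream(t=np.asarray(target_t, float), points=pts, visible=vis)


# ---------------------------------------------------------------------------
# cohort serialization
# ---------------------------------------------------------------------------

def save_cohort(cohort, out_dir: str | Path) -> None:
    """Write a simulated cohort: IMU CSVs, TRC marker files, truth table,
    and a YAML manifest (seed, noise model, session inventory)."""
    from .config import PipelineConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_cfg = PipelineConfig().marker_labels
    manifest = {
        "format": "spinekin-cohort-v1",
        "seed": cohort.seed,
        "noise": cohort.noise.to_dict(),
        "sessions": [],
    }
    for sess in cohort.sessions:
        rel = f"{sess.participant}/trial{sess.trial}"
        sdir = out / rel
        entry = {
            "participant": sess.participant,
            "trial": sess.trial,
            "path": rel,
            "imu_available": sess.imu_available,
            "recordings": sorted(sess.recordings),
        }
        manifest["sessions"].append(entry)
        for label, rec in sess.recordings.items():
            rdir = sdir / label
            rdir.mkdir(parents=True, exist_ok=True)
            if rec.imu is not None:
                for sensor, stream in rec.imu.items():
                    write_imu_csv(stream, rdir / f"imu_{sensor}.csv")
            write_trc(rec.omc, rdir / "markers.trc", labels_cfg)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    if cohort.truth_table is not None:
        cohort.truth_table.to_csv(out / "truth.csv", index=False)


def load_cohort(in_dir: str | Path):
    """Reload a written cohort (truth objects are not reconstructed)."""
    from .config import SENSORS, PipelineConfig
    from .synthetic import Cohort, NoiseModel, RecordingData, SessionData

    root = Path(in_dir)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    if manifest.get("format") != "spinekin-cohort-v1":
        raise DataFormatError(f"{root}: not a spinekin cohort directory")
    labels_cfg = PipelineConfig().marker_labels
    sessions = []
    for entry in manifest["sessions"]:
        sdir = root / entry["path"]
        recordings = {}
        for label in entry["recordings"]:
            rdir = sdir / label
            imu = None
            if entry["imu_available"]:
                imu = {s: read_imu_csv(rdir / f"imu_{s}.csv") for s in SENSORS}
            omc = read_trc(rdir / "markers.trc", labels_cfg)
            recordings[label] = RecordingData(label=label, truth=None, imu=imu, omc=omc)
        sessions.append(SessionData(
            participant=entry["participant"], trial=entry["trial"],
            scenario=None, recordings=recordings, clock_offsets={},
            imu_available=entry["imu_available"],
        ))
    truth = None
    if (root / "truth.csv").exists():
        truth = pd.read_csv(root / "truth.csv")
    return Cohort(sessions=sessions, noise=NoiseModel(**manifest["noise"]),
                  seed=manifest["seed"], truth_table=truth)
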