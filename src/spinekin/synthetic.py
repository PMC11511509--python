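"""Virtual trunk-motion cohort generator.

Generates ground-truth segment kinematics for the full study design - six
range-of-motion movements x five repetitions x two trials per participant -
and renders them simultaneously as IMU quaternion/acceleration streams
(62.5 Hz) and optical marker-cluster trajectories (120 Hz), with
configurable imperfections, so every pipeline stage can be verified by
parameter recovery against known truth.

Study-design defaults mirror the target protocol: four sensors (upper
thoracic T1/T2, thoracolumbar T12/L1, lumbosacral L5/S1, femur), a stomp
acceleration spike for IMU synchronization, a functional-alignment flexion
repetition at the start of each trial, and a static standing tail at the end
of every recording.

Segment orientations are built as a kinematic chain from a pelvis-level base:

    G_L5 = base,  G_T12 = base . R_lumbar,  G_T1 = G_T12 . R_thoracic,
    G_femur = base . R_hip

with each pair rotation composed from raised-cosine repetition profiles in
the movement's Euler order.  Truth peaks equal the commanded amplitudes
exactly; coupled-plane profiles are sinusoids whose whole-trial excursion is
exactly twice the coupled amplitude.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .config import CUED_SIGN, MOVEMENT_ORDER, MOVEMENTS, SEGMENTS, SENSORS
from .dataio import ImuStream, MarkerStream, save_cohort
from .errors import InvalidInputError
from .kinematics import AnglePath
from .rotations import euler_compose_many

GRAVITY = np.array([0.0, 0.0, -9.81])  # global frame is Z-up, m/s^2
MAG_FIELD_UT = np.array([20.0, 0.0, 40.0])  # nominal geomagnetic field, uT

#: typical healthy-adult peak ROM (deg) per (segment, movement)
BASE_AMPLITUDES = {
    ("lumbar", "F"): 50.0, ("thoracic", "F"): 15.0, ("hip", "F"): 60.0,
    ("lumbar", "E"): 20.0, ("thoracic", "E"): 10.0, ("hip", "E"): 15.0,
    ("lumbar", "L_AR"): 10.0, ("thoracic", "L_AR"): 35.0, ("hip", "L_AR"): 15.0,
    ("lumbar", "R_AR"): 10.0, ("thoracic", "R_AR"): 35.0, ("hip", "R_AR"): 15.0,
    ("lumbar", "L_SB"): 25.0, ("thoracic", "L_SB"): 15.0, ("hip", "L_SB"): 20.0,
    ("lumbar", "R_SB"): 25.0, ("thoracic", "R_SB"): 15.0, ("hip", "R_SB"): 20.0,
}

#: default rigid cluster geometry in sensor-local coordinates (mm)
CLUSTER_GEOMETRY = np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0], [0.0, 40.0, 0.0]])
#: nominal sensor positions in the global frame (mm), one per sensor
SENSOR_ORIGINS = {
    "T1T2": np.array([0.0, 0.0, 1450.0]),
    "T12L1": np.array([0.0, 0.0, 1150.0]),
    "L5S1": np.array([0.0, 0.0, 1000.0]),
    "FEMUR": np.array([80.0, 0.0, 700.0]),
}


@dataclass
class NoiseModel:
    """Imperfection model for both measurement systems.

    All defaults are the cohort's standard conditions: consumer-grade
    on-board sensor fusion (sub-degree orientation noise, slow heading
    drift), sub-millimeter optical marker noise with a small soft-tissue
    component, and honest between-trial / between-system variability.
    Use :meth:`noise_free` for exact-recovery checks.
    """

    imu_orientation_noise_deg: float = 0.7
    imu_drift_deg_per_min: float = 1.0
    mounting_sd_deg: float = 5.0
    marker_noise_mm: float = 0.2
    soft_tissue_mm: float = 1.0
    intertrial_amp_sd_deg: float = 2.0
    intersystem_bias_deg: float = 0.0
    intersystem_scatter_deg: float = 3.0
    accel_noise_ms2: float = 0.2
    #: multiplier on the outlier participant's IMU amplitude error, emulating
    #: sensor-fusion anomalies that yield non-physiological ROM values while
    #: calibration and raw data stay intact
    outlier_scale: float = 8.0

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if f_.name != "intersystem_bias_deg" and v < 0:
                raise InvalidInputError(f"noise parameter {f_.name} must be >= 0")

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        return cls(
            imu_orientation_noise_deg=0.0, imu_drift_deg_per_min=0.0,
            mounting_sd_deg=0.0, marker_noise_mm=0.0, soft_tissue_mm=0.0,
            intertrial_amp_sd_deg=0.0, intersystem_bias_deg=0.0,
            intersystem_scatter_deg=0.0, accel_noise_ms2=0.0,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MotionScenario:
    """Commanded kinematics for one participant trial.

    ``amplitudes`` maps (segment, movement) to (signed primary amplitude,
    coupled secondary amplitude, coupled tertiary amplitude) in degrees; the
    primary sign already encodes cued direction and any countermovement.
    ``imu_amplitude_offset_deg`` is added to the primary amplitude magnitude
    when rendering the IMU system only (per-participant inter-system
    perturbation).
    """

    participant: str
    trial: int
    amplitudes: dict
    rep_count: int = 5
    rep_duration_s: float = 3.0
    rest_s: float = 1.0
    lead_in_s: float = 1.0
    static_tail_s: float = 1.0
    cal_flexion_deg: float = 25.0
    imu_amplitude_offset_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for (seg, mov), (a1, a2, a3) in self.amplitudes.items():
            if abs(a1) > 120.0 or abs(a2) > 30.0 or abs(a3) > 30.0:
                raise InvalidInputError(
                    f"amplitudes for {seg}/{mov} outside physiological bounds"
                )
        if not (4 <= self.rep_count <= 5):
            raise InvalidInputError("rep_count must be 4 or 5")


def _bump(u: np.ndarray) -> np.ndarray:
    """Raised cosine, 0 -> 1 -> 0 over u in [0, 1]; zero end velocity."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _coupled(u: np.ndarray) -> np.ndarray:
    """Full-period sinusoid: range [-1, 1], zero at both ends."""
    return np.sin(2.0 * np.pi * u)


@dataclass
class RecordingTruth:
    """Analytic ground truth for one recording (calibration or movement)."""

    label: str  # "cal" or a movement label
    movement: str | None
    order_tag: str
    duration_s: float
    rep_windows: list
    stomp_time_s: float | None
    pair_amplitudes: dict  # segment -> (a1 signed, a2, a3) in slot order
    base_flexion_deg: float = 0.0

    def pair_angles(self, segment: str, t: np.ndarray) -> np.ndarray:
        """(N, 3) Euler slot angles (deg) of the segment pair at times t."""
        t = np.asarray(t, float)
        a1, a2, a3 = self.pair_amplitudes[segment]
        out = np.zeros((t.size, 3))
        for t0, t1 in self.rep_windows:
            u = (t - t0) / (t1 - t0)
            m = (u >= 0.0) & (u <= 1.0)
            out[m, 0] += a1 * _bump(u[m])
            out[m, 1] += a2 * _coupled(u[m])
            out[m, 2] += a3 * _coupled(u[m])
        return out

    def base_rotation(self, t: np.ndarray) -> np.ndarray:
        """Pelvis-level base orientation (N, 3, 3); flexes during calibration."""
        t = np.asarray(t, float)
        ang = np.zeros((t.size, 3))
        if self.base_flexion_deg:
            for t0, t1 in self.rep_windows:
                u = (t - t0) / (t1 - t0)
                m = (u >= 0.0) & (u <= 1.0)
                ang[m, 0] += self.base_flexion_deg * _bump(u[m])
        return euler_compose_many(ang, "FE_SB_AR")

    def sensor_orientations(self, t: np.ndarray,
                            amplitude_offset_deg: float = 0.0) -> dict:
        """Global orientation (N, 3, 3) of each sensor's segment at times t.

        ``amplitude_offset_deg`` inflates every pair's primary amplitude
        magnitude (the inter-system perturbation channel).
        """
        t = np.asarray(t, float)
        pair_R = {}
        for seg in SEGMENTS:
            ang = self.pair_angles(seg, t)
            if amplitude_offset_deg:
                a1 = self.pair_amplitudes[seg][0]
                if a1 != 0.0:
                    scale = (abs(a1) + amplitude_offset_deg) / abs(a1)
                    ang = ang.copy()
                    ang[:, 0] *= max(scale, 0.0)
            pair_R[seg] = euler_compose_many(ang, self.order_tag)
        base = self.base_rotation(t)
        g_t12 = np.einsum("nij,njk->nik", base, pair_R["lumbar"])
        return {
            "L5S1": base,
            "T12L1": g_t12,
            "T1T2": np.einsum("nij,njk->nik", g_t12, pair_R["thoracic"]),
            "FEMUR": np.einsum("nij,njk->nik", base, pair_R["hip"]),
        }

    def angle_path(self, segment: str, rate_hz: float = 120.0,
                   system: str = "truth") -> AnglePath:
        """Ground-truth :class:`AnglePath` sampled at ``rate_hz``."""
        t = np.arange(0.0, self.duration_s, 1.0 / rate_hz)
        return AnglePath(
            segment=segment, system=system,
            movement=self.movement or "F", order_tag=self.order_tag,
            t=t, angles=self.pair_angles(segment, t),
        )


def truth_trajectories(scenario: MotionScenario) -> dict[str, RecordingTruth]:
    """Analytic truth for all recordings of one trial: 'cal' + six movements.

    The calibration recording carries the stomp event, one flexion
    repetition (every segment pair plus the base flexes, so each sensor has
    ample excursion for functional alignment) and a static tail; movement
    recordings carry ``rep_count`` repetitions and end with a static tail of
    at least five frames.
    """
    recs: dict[str, RecordingTruth] = {}
    cal_amp = scenario.cal_flexion_deg
    recs["cal"] = RecordingTruth(
        label="cal", movement=None, order_tag="FE_SB_AR",
        duration_s=7.0, rep_windows=[(1.5, 4.5)], stomp_time_s=0.4,
        pair_amplitudes={seg: (cal_amp, 0.0, 0.0) for seg in SEGMENTS},
        base_flexion_deg=cal_amp,
    )
    movements = [m for m in MOVEMENTS if any(k[1] == m for k in scenario.amplitudes)]
    for mov in movements:
        d, r = scenario.rep_duration_s, scenario.rest_s
        windows = [
            (scenario.lead_in_s + i * (d + r), scenario.lead_in_s + i * (d + r) + d)
            for i in range(scenario.rep_count)
        ]
        duration = windows[-1][1] + r + scenario.static_tail_s
        recs[mov] = RecordingTruth(
            label=mov, movement=mov, order_tag=MOVEMENT_ORDER[mov],
            duration_s=duration, rep_windows=windows, stomp_time_s=None,
            pair_amplitudes={seg: scenario.amplitudes[(seg, mov)] for seg in SEGMENTS},
        )
    return recs


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _smooth_rotvec_noise(rng: np.random.Generator, n: int, sd_deg: float,
                         fs: float, cutoff_hz: float = 5.0) -> np.ndarray:
    """Band-limited orientation noise (N, 3) rotation vectors, radians.

    ``sd_deg`` is the RMS of the *total* angular error (rotation-vector
    magnitude), so the per-axis scale is sd/sqrt(3).
    """
    if sd_deg <= 0 or n == 0:
        return np.zeros((n, 3))
    w = rng.normal(size=(max(n, 32), 3))
    if cutoff_hz < fs / 2:
        sos = butter(2, cutoff_hz / (fs / 2), output="sos")
        w = sosfiltfilt(sos, w, axis=0)
    w = w[:n]
    w = w / max(w.std(), 1e-12)  # per-axis unit variance after filtering
    return np.radians(sd_deg / np.sqrt(3.0)) * w


def random_mountings(rng: np.random.Generator, sd_deg: float) -> dict:
    """Per-sensor local->segment mounting misalignment rotations."""
    out = {}
    for s in SENSORS:
        if sd_deg <= 0:
            out[s] = np.eye(3)
        else:
            out[s] = Rotation.from_rotvec(
                rng.normal(scale=np.radians(sd_deg), size=3)
            ).as_matrix()
    return out


def render_imu(
    truth: RecordingTruth,
    noise: NoiseModel,
    mountings: dict | None = None,
    rate_hz: float = 62.5,
    rng: np.random.Generator | None = None,
    clock_offsets: dict | None = None,
    amplitude_offset_deg: float = 0.0,
    orientation_noise_scale: float = 1.0,
) -> dict[str, ImuStream]:
    """Render per-sensor IMU streams (quaternion + accel + gyro + mag).

    The measured orientation is drift . noise . G_segment . mounting; the
    accelerometer reports specific force (gravity reaction in the sensor
    frame) plus the stomp spike (a >= 4 g half-sine at the stomp time) and
    white noise.  Timestamps are shifted by the per-sensor clock offset.
    """
    rng = rng or np.random.default_rng(0)
    mountings = mountings or {s: np.eye(3) for s in SENSORS}
    clock_offsets = clock_offsets or {s: 0.0 for s in SENSORS}
    t = np.arange(0.0, truth.duration_s, 1.0 / rate_hz)
    n = t.size
    seg_R = truth.sensor_orientations(t, amplitude_offset_deg)
    sd = noise.imu_orientation_noise_deg * orientation_noise_scale
    streams = {}
    for s in SENSORS:
        R = np.einsum("nij,jk->nik", seg_R[s], mountings[s])
        if sd > 0:
            E = Rotation.from_rotvec(_smooth_rotvec_noise(rng, n, sd, rate_hz)).as_matrix()
            R = np.einsum("nij,njk->nik", E, R)
        if noise.imu_drift_deg_per_min > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.radians(noise.imu_drift_deg_per_min) * (t / 60.0)
            D = Rotation.from_rotvec(np.outer(ang, axis)).as_matrix()
            R = np.einsum("nij,njk->nik", D, R)
        rot = Rotation.from_matrix(R)
        quat = rot.as_quat(scalar_first=True)
        # specific force: -gravity expressed in the sensor frame
        f_global = np.tile(-GRAVITY, (n, 1))
        if truth.stomp_time_s is not None:
            u = (t - truth.stomp_time_s) / 0.06
            m = (u >= 0) & (u <= 1)
            f_global[m, 2] += 50.0 * np.sin(np.pi * u[m])  # > 4 g spike
        accel = np.einsum("nji,nj->ni", R, f_global)
        if noise.accel_noise_ms2 > 0:
            accel = accel + rng.normal(scale=noise.accel_noise_ms2, size=accel.shape)
        # angular velocity from finite orientation differences (local frame)
        gyro = np.zeros((n, 3))
        if n > 1:
            dq = (rot[:-1].inv() * rot[1:]).as_rotvec() * rate_hz
            gyro[1:] = dq
            gyro[0] = gyro[1]
        mag = np.einsum("nji,j->ni", R, MAG_FIELD_UT)
        streams[s] = ImuStream(
            t=t + clock_offsets[s], quat_wxyz=quat, accel=accel, gyro=gyro, mag=mag
        )
    return streams


def render_omc(
    truth: RecordingTruth,
    noise: NoiseModel,
    mountings: dict | None = None,
    cluster_geometry: np.ndarray = CLUSTER_GEOMETRY,
    rate_hz: float = 120.0,
    rng: np.random.Generator | None = None,
    occlusions: list | None = None,
) -> dict[str, MarkerStream]:
    """Render per-sensor rigid-cluster marker trajectories (mm, global).

    Markers are rigidly transported by the segment motion, then perturbed by
    Gaussian position noise and a low-frequency sinusoidal soft-tissue
    displacement (which breaks cluster rigidity slightly).  ``occlusions`` is
    a list of (sensor, t_start, t_end) windows whose frames become missing.
    """
    rng = rng or np.random.default_rng(0)
    mountings = mountings or {s: np.eye(3) for s in SENSORS}
    t = np.arange(0.0, truth.duration_s, 1.0 / rate_hz)
    n = t.size
    seg_R = truth.sensor_orientations(t)
    streams = {}
    for s in SENSORS:
        R = np.einsum("nij,jk->nik", seg_R[s], mountings[s])
        pts = np.einsum("nij,mj->nmi", R, cluster_geometry) + SENSOR_ORIGINS[s]
        if noise.soft_tissue_mm > 0:
            # markers share one rigid casing, so skin/clothing artifact is
            # mostly a common-mode displacement of the whole cluster, with a
            # small independent per-marker component perturbing rigidity
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            phase = rng.uniform(0, 2 * np.pi)
            disp = noise.soft_tissue_mm * np.sin(2 * np.pi * 0.8 * t + phase)
            pts += disp[:, None, None] * direction
            for m in range(3):
                d_m = rng.normal(size=3)
                d_m /= np.linalg.norm(d_m)
                ph_m = rng.uniform(0, 2 * np.pi)
                disp_m = 0.2 * noise.soft_tissue_mm * np.sin(2 * np.pi * 0.8 * t + ph_m)
                pts[:, m, :] += disp_m[:, None] * d_m
        if noise.marker_noise_mm > 0:
            pts = pts + rng.normal(scale=noise.marker_noise_mm, size=pts.shape)
        visible = np.ones((n, 3), dtype=bool)
        for sensor, t0, t1 in occlusions or []:
            if sensor == s:
                visible[(t >= t0) & (t <= t1), :] = False
        pts[~visible] = np.nan
        streams[s] = MarkerStream(t=t, points=pts, visible=visible)
    return streams


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class RecordingData:
    label: str
    truth: RecordingTruth
    imu: dict | None  # sensor -> ImuStream (None if battery-depleted)
    omc: dict  # sensor -> MarkerStream


@dataclass
class SessionData:
    participant: str
    trial: int
    scenario: MotionScenario
    recordings: dict  # label -> RecordingData
    clock_offsets: dict
    imu_available: bool = True


@dataclass
class Cohort:
    sessions: list
    noise: NoiseModel
    seed: int
    truth_table: "object" = None  # pandas DataFrame of commanded amplitudes

    def session(self, participant: str, trial: int) -> SessionData:
        for s in self.sessions:
            if s.participant == participant and s.trial == trial:
                return s
        raise KeyError((participant, trial))

    @property
    def participants(self) -> list:
        return sorted({s.participant for s in self.sessions})


def make_cohort(
    n_participants: int = 16,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_trials: int = 2,
    movements: tuple = MOVEMENTS,
    rep_count: int = 5,
    rep_duration_s: float = 3.0,
    rest_s: float = 1.0,
    amplitude_spread: float = 0.15,
    countermovement_prob: float = 0.12,
    include_outlier_participant: bool = False,
    include_battery_depletion: bool = False,
    include_occlusion: bool = False,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Simulate a full cohort; optionally write it to disk.

    Per participant, base amplitudes are drawn once (multiplicative
    between-subject spread) and perturbed per trial by the inter-trial SD;
    the lumbar segment occasionally countermoves during axial rotation.  The
    IMU system sees each participant's primary amplitudes inflated by
    bias + N(0, scatter^2) - the inter-system perturbation channel.  Optional
    injections: one outlier participant (scaled IMU orientation noise), one
    battery-depleted trial (no IMU data at trial 2), one movement recording
    with a fully occluded T12/L1 cluster.
    """
    import pandas as pd

    if n_participants < 3:
        raise InvalidInputError("cohort needs at least 3 participants")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    sessions = []
    truth_rows = []
    pids = [f"S{i + 1:02d}" for i in range(n_participants)]
    outlier_pid = pids[-1] if include_outlier_participant else None
    battery_pid = pids[0] if include_battery_depletion else None
    occl_target = (pids[min(1, n_participants - 1)], 1, "R_AR") if include_occlusion else None

    for pid in pids:
        mult = {
            seg: float(np.clip(rng.normal(1.0, amplitude_spread), 0.5, 1.5))
            for seg in SEGMENTS
        }
        coupled = {
            (seg, mov): (float(rng.uniform(1.0, 6.0)), float(rng.uniform(0.5, 4.0)))
            for seg in SEGMENTS for mov in movements
        }
        counter = {
            mov: (rng.uniform() < countermovement_prob)
            for mov in movements if mov in ("L_AR", "R_AR")
        }
        delta = noise.intersystem_bias_deg + rng.normal(
            scale=noise.intersystem_scatter_deg
        ) if (noise.intersystem_bias_deg or noise.intersystem_scatter_deg) else 0.0
        if pid == outlier_pid:
            # non-physiologically high IMU values, calibration left intact
            delta = noise.outlier_scale * max(abs(delta), 3.0)
        for trial in range(1, n_trials + 1):
            amplitudes = {}
            for seg in SEGMENTS:
                for mov in movements:
                    base = BASE_AMPLITUDES[(seg, mov)] * mult[seg]
                    jitter = rng.normal(scale=noise.intertrial_amp_sd_deg) if noise.intertrial_amp_sd_deg else 0.0
                    mag = max(base + jitter, 3.0)
                    sign = CUED_SIGN[mov]
                    if seg == "lumbar" and counter.get(mov, False):
                        sign, mag = -sign, min(mag, 8.0)  # countermovement strategy
                    a2, a3 = coupled[(seg, mov)]
                    amplitudes[(seg, mov)] = (sign * mag, a2, a3)
                    truth_rows.append({
                        "participant": pid, "trial": trial, "segment": seg,
                        "movement": mov, "amplitude_deg": mag, "direction": sign,
                        "coupled_secondary_deg": a2, "coupled_tertiary_deg": a3,
                        "imu_offset_deg": delta,
                    })
            scenario = MotionScenario(
                participant=pid, trial=trial, amplitudes=amplitudes,
                rep_count=rep_count, rep_duration_s=rep_duration_s, rest_s=rest_s,
                imu_amplitude_offset_deg=delta,
                seed=int(rng.integers(2**31 - 1)),
            )
            truths = truth_trajectories(scenario)
            mnt = random_mountings(rng, noise.mounting_sd_deg)
            offsets = {s: float(rng.uniform(-0.3, 0.3)) for s in SENSORS}
            imu_ok = not (battery_pid == pid and trial == n_trials)
            recordings = {}
            for label, tr in truths.items():
                occl = None
                if occl_target and (pid, trial, label) == occl_target:
                    occl = [("T12L1", 0.0, tr.duration_s)]
                imu = render_imu(
                    tr, noise, mnt, rng=rng, clock_offsets=offsets,
                    amplitude_offset_deg=delta,
                ) if imu_ok else None
                omc = render_omc(tr, noise, mnt, rng=rng, occlusions=occl)
                recordings[label] = RecordingData(label=label, truth=tr, imu=imu, omc=omc)
            sessions.append(SessionData(
                participant=pid, trial=trial, scenario=scenario,
                recordings=recordings, clock_offsets=offsets, imu_available=imu_ok,
            ))

    cohort = Cohort(
        sessions=sessions, noise=noise, seed=seed,
        truth_table=pd.DataFrame(truth_rows),
    )
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort
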