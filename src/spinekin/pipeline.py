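"""End-to-end orchestration: cohort -> calibrations -> angle paths ->
segment-movement summaries -> agreement report.

Each participant trial contributes one calibration recording (stomp,
functional flexion repetition, static tail) and six movement recordings.
Per system the flow is:

1. estimate per-sensor clock offsets from the stomp (IMU only) and resample
   the four streams onto one timeline;
2. functional body calibration per sensor (flexion repetition + static pose);
3. four-factor relative rotation per segment pair, static normalization on
   the trial's trailing frames, Euler decomposition in the movement's order;
4. repetition segmentation on the whole-trunk reference trace (falling back
   to a segment's own trace when it leads or lags the reference), peak
   extraction with the countermovement rule, summary per segment movement.

Every exclusion (battery depletion, cluster occlusion, failed segmentation,
failed calibration) is a logged, categorized event carried into the report's
per-row N.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dataio import ImuStream, MarkerStream, resample_imu, sync_imus
from .errors import DataError, SegmentationFailureError, TooFewRepetitionsError
from .frames import (
    BodyCalibration,
    build_body_calibration,
    cluster_orientations,
    functional_ml_axis,
    vertical_axis_imu,
    vertical_axis_omc,
)
from .kinematics import (
    AnglePath,
    angle_path,
    lowpass_rotations,
    normalize_to_static,
    relative_rotation_path,
)
from .rom import SegmentMovementSummary, segment_repetitions, summarize

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Exclusion:
    participant: str
    trial: int
    system: str
    segment: str  # "" = whole trial/system
    movement: str  # "" = all movements
    category: str  # battery | occlusion | calibration | segmentation | data
    message: str


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def imu_calibrations(cal_streams: dict[str, ImuStream],
                     config: PipelineConfig) -> dict[str, BodyCalibration]:
    """Functional body calibration per sensor from the calibration recording."""
    out = {}
    for sensor, stream in cal_streams.items():
        R = stream.rotations()
        ml = functional_ml_axis(R, config.functional_min_excursion_deg)
        n_static = max(2, int(round(config.static_window_s
                                    * config.imu_rate_hz)))
        vert = vertical_axis_imu(R[-n_static:], config.static_max_excursion_deg)
        out[sensor] = build_body_calibration(
            ml, vert, sensor_id=sensor, system="IMU",
            min_angle_deg=config.axes_min_angle_deg,
        )
    return out


def omc_calibrations(cal_streams: dict[str, MarkerStream],
                     config: PipelineConfig) -> dict[str, BodyCalibration]:
    out = {}
    for sensor, stream in cal_streams.items():
        R, valid = cluster_orientations(stream.points, stream.visible)
        if valid.sum() < 10:
            raise DataError(f"{sensor}: too few visible calibration frames")
        Rv = R[valid]
        ml = functional_ml_axis(Rv, config.functional_min_excursion_deg)
        n_static = max(2, int(round(config.static_window_s * config.omc_rate_hz)))
        vert = vertical_axis_omc(Rv[-n_static:], config.static_max_excursion_deg)
        out[sensor] = build_body_calibration(
            ml, vert, sensor_id=sensor, system="OMC",
            min_angle_deg=config.axes_min_angle_deg,
        )
    return out


def save_calibrations(cals: dict, path) -> None:
    """Sidecar YAML of calibration matrices for reproducibility."""
    import yaml

    payload = {k: v.to_dict() for k, v in cals.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-recording processing
# ---------------------------------------------------------------------------

def _imu_orientation_matrix(streams: dict[str, ImuStream],
                            offsets: dict[str, float],
                            rate_hz: float) -> tuple[np.ndarray, dict]:
    """Align the four IMU streams and return a shared timeline + rotations."""
    aligned = {s: st.shifted(offsets.get(s, 0.0)) for s, st in streams.items()}
    t0 = max(st.t[0] for st in aligned.values())
    t1 = min(st.t[-1] for st in aligned.values())
    t = np.arange(t0, t1, 1.0 / rate_hz)
    R = {s: resample_imu(st, t).rotations() for s, st in aligned.items()}
    return t, R


def _pair_paths(
    t: np.ndarray,
    R: dict[str, np.ndarray],
    cals: dict[str, BodyCalibration],
    movement: str,
    system: str,
    config: PipelineConfig,
    usable: set[str],
) -> tuple[dict[str, AnglePath], AnglePath | None]:
    """Angle paths for the three segment pairs plus the reference pair."""
    paths = {}
    for segment, (distal, proximal) in config.pairing.items():
        if distal not in usable or proximal not in usable:
            continue
        s1, s2 = (distal, proximal) if config.s1_is_distal else (proximal, distal)
        rel = relative_rotation_path(R[s1], R[s2], cals[s1], cals[s2])
        rel = lowpass_rotations(rel, t, config.angle_lowpass_hz)
        rel = normalize_to_static(rel, config.n_static_frames)
        paths[segment] = angle_path(rel, movement, t, segment=segment,
                                    system=system)
    ref = None
    rd, rp = config.reference_pair
    if rd in usable and rp in usable:
        rel = relative_rotation_path(R[rd], R[rp], cals[rd], cals[rp])
        rel = lowpass_rotations(rel, t, config.angle_lowpass_hz)
        rel = normalize_to_static(rel, config.n_static_frames)
        ref = angle_path(rel, movement, t, segment="trunk", system=system)
    return paths, ref


def _summaries_for_paths(
    paths: dict[str, AnglePath],
    ref: AnglePath | None,
    participant: str,
    trial: int,
    config: PipelineConfig,
) -> tuple[list[SegmentMovementSummary], list[Exclusion]]:
    summaries, exclusions = [], []
    seg_kwargs = dict(
        expected_n=config.expected_repetitions,
        lowpass_hz=config.seg_lowpass_hz,
        min_prominence_deg=config.seg_min_prominence_deg,
        min_separation_s=config.seg_min_separation_s,
    )
    ref_reps = None
    if ref is not None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ref_reps = segment_repetitions(ref, **seg_kwargs)
        except SegmentationFailureError as e:
            log.warning("reference segmentation failed: %s", e)
    for segment, path in paths.items():
        system = path.system
        movement = path.movement
        reps = ref_reps
        # lag fallback: when a segment leads or lags the whole-trunk
        # reference so that some reference window truncates its repetition,
        # re-segment on that segment's own trace (keeping the reference
        # windows if that fails)
        if reps is not None and config.per_segment_fallback:
            whole = float(np.max(np.abs(path.primary)))
            ratios = [
                float(np.max(np.abs(path.primary[r.start:r.end]))) / whole
                for r in reps
            ] if whole > 0 else [1.0]
            if min(ratios) < config.lag_fallback_ratio:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        reps = segment_repetitions(path, **seg_kwargs)
                    log.info("%s/%s %s: re-segmented on the segment's own trace",
                             segment, movement, system)
                except SegmentationFailureError:
                    pass
        if reps is None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    reps = segment_repetitions(path, **seg_kwargs)
            except SegmentationFailureError as e:
                exclusions.append(Exclusion(
                    participant, trial, system, segment, movement,
                    "segmentation", str(e)))
                continue
        try:
            summaries.append(summarize(
                path, reps, participant=participant, trial=trial,
                min_reps=config.min_repetitions,
            ))
        except TooFewRepetitionsError as e:
            exclusions.append(Exclusion(
                participant, trial, system, segment, movement,
                "segmentation", str(e)))
    return summaries, exclusions


# ---------------------------------------------------------------------------
# session / cohort drivers
# ---------------------------------------------------------------------------

def process_session(session, config: PipelineConfig | None = None
                    ) -> tuple[list[SegmentMovementSummary], list[Exclusion]]:
    """All segment-movement summaries (both systems) for one participant trial."""
    config = config or PipelineConfig()
    summaries: list[SegmentMovementSummary] = []
    exclusions: list[Exclusion] = []
    pid, trial = session.participant, session.trial
    cal_rec = session.recordings.get("cal")
    if cal_rec is None:
        exclusions.append(Exclusion(pid, trial, "", "", "", "data",
                                    "no calibration recording"))
        return summaries, exclusions

    # ----- IMU side
    imu_cals = offsets = None
    if session.imu_available and cal_rec.imu is not None:
        try:
            offsets = sync_imus(cal_rec.imu, config.stomp_min_height_ms2,
                                config.stomp_ambiguity_ratio)
            imu_cals = imu_calibrations(cal_rec.imu, config)
        except DataError as e:
            exclusions.append(Exclusion(pid, trial, "IMU", "", "",
                                        "calibration", str(e)))
    else:
        exclusions.append(Exclusion(pid, trial, "IMU", "", "", "battery",
                                    "IMU data unavailable for this trial"))

    # ----- OMC side
    omc_cals = None
    omc_usable = set()
    try:
        usable_streams = {}
        for sensor, ms in cal_rec.omc.items():
            if np.mean(ms.visible.all(axis=1)) >= 0.5:
                usable_streams[sensor] = ms
            else:
                exclusions.append(Exclusion(
                    pid, trial, "OMC", "", "", "occlusion",
                    f"{sensor} cluster occluded during calibration"))
        omc_cals = omc_calibrations(usable_streams, config)
        omc_usable = set(omc_cals)
    except DataError as e:
        exclusions.append(Exclusion(pid, trial, "OMC", "", "",
                                    "calibration", str(e)))
        omc_cals = None

    for label, rec in session.recordings.items():
        if label == "cal":
            continue
        movement = label
        if imu_cals is not None and rec.imu is not None:
            try:
                t, R = _imu_orientation_matrix(rec.imu, offsets, config.imu_rate_hz)
                paths, ref = _pair_paths(t, R, imu_cals, movement, "IMU",
                                         config, set(R))
                s, e = _summaries_for_paths(paths, ref, pid, trial, config)
                summaries.extend(s)
                exclusions.extend(e)
            except DataError as e:
                exclusions.append(Exclusion(pid, trial, "IMU", "", movement,
                                            "data", str(e)))
        elif imu_cals is not None and rec.imu is None:
            exclusions.append(Exclusion(pid, trial, "IMU", "", movement,
                                        "battery", "no IMU data"))
        if omc_cals is not None:
            try:
                usable, R, tgrid = _omc_rotations(rec.omc, omc_usable, config)
                for sensor in omc_usable - usable:
                    for segment, pair in config.pairing.items():
                        if sensor in pair:
                            exclusions.append(Exclusion(
                                pid, trial, "OMC", segment, movement,
                                "occlusion", f"{sensor} cluster occluded"))
                paths, ref = _pair_paths(tgrid, R, omc_cals, movement, "OMC",
                                         config, usable)
                s, e = _summaries_for_paths(paths, ref, pid, trial, config)
                summaries.extend(s)
                exclusions.extend(e)
            except DataError as e:
                exclusions.append(Exclusion(pid, trial, "OMC", "", movement,
                                            "data", str(e)))
    return summaries, exclusions


def _omc_rotations(omc: dict[str, MarkerStream], usable_cal: set,
                   config: PipelineConfig):
    """Cluster orientations on the frames where every usable sensor is visible."""
    R_all, valid_all, usable = {}, {}, set()
    t = None
    for sensor, ms in omc.items():
        if sensor not in usable_cal:
            continue
        R, valid = cluster_orientations(ms.points, ms.visible)
        if valid.mean() >= 0.5:
            usable.add(sensor)
            R_all[sensor] = R
            valid_all[sensor] = valid
            t = ms.t
    if not usable or t is None:
        raise DataError("no usable marker clusters in recording")
    common = np.logical_and.reduce([valid_all[s] for s in usable])
    return usable, {s: R_all[s][common] for s in usable}, t[common]


def cohort_summaries(cohort, config: PipelineConfig | None = None
                     ) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Tidy summary table for a whole cohort plus the exclusion log."""
    config = config or PipelineConfig()
    rows, exclusions = [], []
    for session in cohort.sessions:
        s, e = process_session(session, config)
        rows.extend(dataclass_rows(s))
        exclusions.extend(e)
    df = pd.DataFrame(rows, columns=[
        "participant", "trial", "system", "segment", "movement",
        "mean_peak_primary", "excursion_secondary", "excursion_tertiary",
        "n_reps",
    ])
    for ex in exclusions:
        log.info("exclusion [%s] %s trial %s %s/%s (%s): %s", ex.category,
                 ex.participant, ex.trial, ex.segment or "-", ex.movement or "-",
                 ex.system, ex.message)
    return df, exclusions


def dataclass_rows(items) -> list[dict]:
    import dataclasses

    return [dataclasses.asdict(i) for i in items]


def run_cohort_report(cohort, config: PipelineConfig | None = None,
                      out_dir=None) -> dict:
    """Full pipeline: summaries, exclusions, agreement tables, run metadata."""
    from .stats import build_report

    config = config or PipelineConfig()
    summaries, exclusions = cohort_summaries(cohort, config)
    report = build_report(summaries, config, out_dir=out_dir)
    report["summaries"] = summaries
    report["exclusions"] = pd.DataFrame(dataclass_rows(exclusions), columns=[
        "participant", "trial", "system", "segment", "movement", "category",
        "message"])
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        summaries.to_csv(out / "summaries.csv", index=False)
        report["exclusions"].to_csv(out / "exclusions.csv", index=False)
        run_meta = {
            "config_hash": config.config_hash(),
            "n_participants": int(summaries["participant"].nunique()),
            "n_summaries": int(len(summaries)),
            "n_exclusions": int(len(report["exclusions"])),
        }
        import json

        (out / "run_summary.json").write_text(json.dumps(run_meta, indent=2))
    return report
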