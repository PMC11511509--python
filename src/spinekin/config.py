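"""Pipeline configuration.

A single flat dataclass holds every tunable threshold and naming convention;
it round-trips through YAML and hashes deterministically so a run can be
reproduced from its logged config hash.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError

SENSORS = ("T1T2", "T12L1", "L5S1", "FEMUR")
SEGMENTS = ("lumbar", "thoracic", "hip")
MOVEMENTS = ("F", "E", "L_AR", "R_AR", "L_SB", "R_SB")

#: movement label -> Euler decomposition order
MOVEMENT_ORDER = {
    "F": "FE_SB_AR",
    "E": "FE_SB_AR",
    "L_AR": "AR_FE_SB",
    "R_AR": "AR_FE_SB",
    "L_SB": "SB_FE_AR",
    "R_SB": "SB_FE_AR",
}
#: movement label -> sign of the cued direction in the primary plane
CUED_SIGN = {"F": 1.0, "E": -1.0, "L_AR": 1.0, "R_AR": -1.0, "L_SB": 1.0, "R_SB": -1.0}


def _default_pairing() -> dict[str, tuple[str, str]]:
    # segment -> (distal sensor, proximal sensor)
    return {
        "thoracic": ("T1T2", "T12L1"),
        "lumbar": ("T12L1", "L5S1"),
        "hip": ("FEMUR", "L5S1"),
    }


def _default_marker_labels() -> dict[str, tuple[str, str, str]]:
    return {s: (f"{s}_1", f"{s}_2", f"{s}_3") for s in SENSORS}


@dataclass
class PipelineConfig:
    # sampling
    imu_rate_hz: float = 62.5
    omc_rate_hz: float = 120.0
    # calibration
    static_window_s: float = 0.5
    static_max_excursion_deg: float = 2.0
    functional_min_excursion_deg: float = 15.0
    axes_min_angle_deg: float = 10.0
    # static normalization
    n_static_frames: int = 5
    # kinematic trace conditioning (zero-phase low-pass; 0 disables).
    # ~10x the repetition fundamental (one 3 s repetition ~ 0.33 Hz)
    angle_lowpass_hz: float = 3.0
    # repetition segmentation (automated stand-in for visual inspection)
    seg_lowpass_hz: float = 2.0
    seg_min_prominence_deg: float = 5.0
    seg_min_separation_s: float = 1.5
    # ROM extraction
    min_repetitions: int = 4
    expected_repetitions: int = 5
    # re-segment on a segment's own trace when it leads/lags the reference
    per_segment_fallback: bool = True
    lag_fallback_ratio: float = 0.6
    # synchronization
    stomp_min_height_ms2: float = 25.0
    stomp_ambiguity_ratio: float = 0.8
    # resampling
    max_gap_s: float = 0.25
    # statistics
    icc_model: str = "ICC2_1"  # one of ICC2_1 | ICC3_1 | ICC2_k
    icc_ci: float = 0.95
    outlier_sd_threshold: float = 2.0
    # wiring
    pairing: dict = field(default_factory=_default_pairing)
    reference_pair: tuple[str, str] = ("T1T2", "L5S1")
    s1_is_distal: bool = True
    marker_labels: dict = field(default_factory=_default_marker_labels)

    def __post_init__(self) -> None:
        if self.icc_model not in ("ICC2_1", "ICC3_1", "ICC2_k"):
            raise ConfigError(f"unknown ICC model {self.icc_model!r}")
        if self.n_static_frames < 1:
            raise ConfigError("n_static_frames must be >= 1")
        pairing = {k: tuple(v) for k, v in self.pairing.items()}
        used = {s for pair in pairing.values() for s in pair}
        if not used.issubset(set(SENSORS)):
            raise ConfigError(f"pairing references unknown sensors: {used - set(SENSORS)}")
        self.pairing = pairing
        self.reference_pair = tuple(self.reference_pair)
        self.marker_labels = {k: tuple(v) for k, v in self.marker_labels.items()}

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pairing"] = {k: list(v) for k, v in self.pairing.items()}
        d["reference_pair"] = list(self.reference_pair)
        d["marker_labels"] = {k: list(v) for k, v in self.marker_labels.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config file {path}: {e}") from e
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
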