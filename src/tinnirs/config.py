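"""Run configuration: every tunable constant of the pipeline in one place.

Defaults equal the study parameters: gain threshold 7, SCI threshold
0.75 in the 0.2–2.5 Hz band, 1 Hz resting resample, 0.01–0.12 Hz
8th-order zero-phase evoked band, -5..30 s epochs with 2.5 SD rejection,
0–5 s auditory and 10–15 s visual windows, information-gain thresholds
0.45/0.56, KNN k=1 and 10-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .simulate import CohortConfig


@dataclass
class RunConfig:
    seed: int = 0
    montage_variant: str = "default"
    schedule: dict = field(default_factory=dict)
    gain_threshold: int = 7
    sci_threshold: float = 0.75
    sci_band_hz: tuple = (0.2, 2.5)
    resting_target_hz: float = 1.0
    wavelet_outlier_threshold: float = 3.0
    evoked_band_hz: tuple = (0.01, 0.12)
    filter_order: int = 8
    epoch_window_s: tuple = (-5.0, 30.0)
    reject_sd: float = 2.5
    ar_max_order: int | None = None  # None -> ceil(4*log10(n))
    robust_correlation: bool = True
    fisher_z_roi_average: bool = False
    ig_bins: int = 5
    ig_thresholds: dict = field(
        default_factory=lambda: {
            "auditory": 0.45, "visual": 0.45, "connectivity": 0.45, "combined": 0.56
        }
    )
    knn_k: int = 1
    ann_hidden: int = 10
    cv_folds: int = 10
    severity_binary_threshold: float = 36.0  # THI <= 36 -> slight/mild
    bh_correction: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)

    # ------------------------------------------------------------- IO

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(
                **{
                    k: tuple(v) if k == "severity_counts" else v
                    for k, v in d["cohort"].items()
                }
            )
        for key in ("sci_band_hz", "evoked_band_hz", "epoch_window_s"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]
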