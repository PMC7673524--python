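"""End-to-end per-subject processing and cohort feature-table assembly.

Fixed processing order (recorded in each recording's provenance):

resting branch
    QC -> optical density -> resting-period slice -> 1 Hz resample ->
    short-channel correction -> Beer-Lambert -> whitened seed
    connectivity;
evoked branch
    QC -> optical density -> wavelet motion correction -> short-channel
    correction -> 0.01–0.12 Hz band-pass -> Beer-Lambert -> epoching ->
    2.5 SD rejection -> window means.

Short-channel correction runs after resampling on the resting branch
(both series resampled identically) and before band-pass filtering on
the evoked branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import RunConfig
from .connectivity import ConnectivityResult, seed_roi_connectivity
from .evoked import (
    EvokedFeatures,
    bandpass_recording,
    extract_epochs,
    reject_epochs,
    wavelet_motion_correct,
    window_mean_features,
)
from .preprocess import (
    QcReport,
    apply_qc,
    beer_lambert,
    downsample_resting,
    intensity_to_od,
    short_channel_correct,
)
from .recording import Recording
from .simulate import SimulatedSubject

MODALITY_PREFIX = {"auditory": "aud", "visual": "vis"}
METADATA_COLUMNS = (
    "subject", "group", "thi", "loudness", "annoyance", "duration_years",
    "age", "hearing_4k", "hearing_8k",
)


@dataclass
class SubjectResult:
    qc: QcReport
    connectivity: ConnectivityResult | None
    evoked: EvokedFeatures | None
    features: dict[str, float]


def connectivity_feature_name(side: str, roi: str, chrom: str, channel: int) -> str:
    return f"conn_{side}_{roi}_{chrom}_ch{channel}"


def evoked_feature_name(modality: str, chrom: str, channel: int) -> str:
    return f"{MODALITY_PREFIX[modality]}_{chrom}_ch{channel}"


def process_subject(raw: Recording, config: RunConfig | None = None) -> SubjectResult:
    """Run the full preprocessing and feature-extraction chain on one subject."""
    config = config or RunConfig()
    schedule = raw.schedule
    if schedule is None:
        raise ValueError("recording carries no stimulus schedule")

    kept, qc = apply_qc(raw, config.gain_threshold, config.sci_threshold)
    od = intensity_to_od(kept)

    # ---- resting branch
    connectivity = None
    features: dict[str, float] = {}
    try:
        rest = od.slice_time(schedule.resting_slice)
        rest = downsample_resting(rest, config.resting_target_hz)
        rest = short_channel_correct(rest)
        rest_hemo = beer_lambert(rest)
        connectivity = seed_roi_connectivity(
            rest_hemo, max_order=config.ar_max_order, robust=config.robust_correlation
        )
        for row in connectivity.table.itertuples():
            features[
                connectivity_feature_name(row.seed_side, row.roi, row.chromophore, row.channel)
            ] = row.r
    except ValueError:
        pass  # no resting period in this schedule variant

    # ---- evoked branch
    evoked = None
    if schedule.blocks:
        ev = wavelet_motion_correct(od, config.wavelet_outlier_threshold)
        ev = short_channel_correct(ev)
        ev = bandpass_recording(ev, config.evoked_band_hz, config.filter_order)
        ev_hemo = beer_lambert(ev)
        epochs = extract_epochs(ev_hemo, schedule, config.epoch_window_s)
        epochs = reject_epochs(epochs, config.reject_sd)
        montage = raw.montage
        evoked = window_mean_features(epochs, montage)
        long_ids = set(montage.long_ids)
        for row in evoked.table.itertuples():
            if row.channel in long_ids:
                features[evoked_feature_name(row.modality, row.chromophore, row.channel)] = row.value

    return SubjectResult(qc=qc, connectivity=connectivity, evoked=evoked, features=features)


def subject_metadata(sim: SimulatedSubject) -> dict:
    spec = sim.spec
    return {
        "subject": sim.subject_id,
        "group": spec.group,
        "thi": spec.thi,
        "loudness": spec.loudness,
        "annoyance": spec.annoyance,
        "duration_years": spec.duration_years,
        "age": spec.age,
        "hearing_4k": spec.hearing_4k,
        "hearing_8k": spec.hearing_8k,
    }


def cohort_feature_table(
    subjects: Iterable[SimulatedSubject], config: RunConfig | None = None
) -> pd.DataFrame:
    """Process a cohort (streaming) into a per-subject feature table.

    Features missing for a subject (rejected channels) are NaN.
    """
    rows = []
    for sim in subjects:
        result = process_subject(sim.recording, config)
        row = subject_metadata(sim)
        row.update(result.features)
        rows.append(row)
    table = pd.DataFrame(rows)
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    feat = sorted(c for c in table.columns if c not in METADATA_COLUMNS)
    return table[meta + feat]


def feature_columns(table: pd.DataFrame, feature_set: str = "combined") -> list[str]:
    """Column names of a named feature set: auditory, visual, connectivity, combined."""
    prefixes = {
        "auditory": ("aud_",),
        "visual": ("vis_",),
        "connectivity": ("conn_",),
        "combined": ("aud_", "vis_", "conn_"),
    }
    if feature_set not in prefixes:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return [c for c in table.columns if c.startswith(prefixes[feature_set])]


def roi_summary_features(table: pd.DataFrame) -> pd.DataFrame:
    """ROI-averaged summary features used for the group statistics.

    Auditory/visual window means averaged over the corresponding ROI
    channels and seed connectivity averaged per ROI, per chromophore.
    """
    from .montage import build_montage

    montage = build_montage()
    out = table[[c for c in METADATA_COLUMNS if c in table.columns]].copy()
    for chrom in ("HbO", "HbR"):
        for roi, prefix in (("left_temporal", "aud"), ("right_temporal", "aud"), ("occipital", "vis")):
            cols = [
                f"{prefix}_{chrom}_ch{cid}"
                for cid in sorted(montage.roi[roi])
                if f"{prefix}_{chrom}_ch{cid}" in table.columns
            ]
            if cols:
                out[f"{prefix}_{roi}_{chrom}"] = table[cols].mean(axis=1)
        for side in ("left", "right"):
            for roi in ("frontal", "occipital"):
                cols = [
                    c for c in table.columns if c.startswith(f"conn_{side}_{roi}_{chrom}_")
                ]
                if cols:
                    out[f"conn_{side}_{roi}_{chrom}"] = table[cols].mean(axis=1)
    if {"aud_left_temporal_HbO", "aud_right_temporal_HbO"} <= set(out.columns):
        for chrom in ("HbO", "HbR"):
            out[f"aud_bilateral_{chrom}"] = out[
                [f"aud_left_temporal_{chrom}", f"aud_right_temporal_{chrom}"]
            ].mean(axis=1)
    return out
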