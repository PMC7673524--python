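"""Evoked-response extraction: motion correction, filtering, epoching, features.

The evoked chain runs at the native 7.8125 Hz sampling rate on optical
density: wavelet-based motion-artefact suppression, zero-phase 8th-order
Butterworth high-pass (0.01 Hz) then low-pass (0.12 Hz), conversion to
HbO/HbR, epoching from -5 to +30 s around each stimulus onset with
linear detrending and baseline correction, rejection of epochs whose
amplitude exceeds 2.5 SD above the epoch mean, and window-mean features
over 0–5 s (auditory, response rise) and 10–15 s (visual, sustained
response) of the averaged trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .montage import Montage
from .recording import CHROMOPHORES, Recording
from .schedule import StimulusSchedule

EVOKED_BAND_HZ = (0.01, 0.12)
FILTER_ORDER = 8
EPOCH_WINDOW_S = (-5.0, 30.0)
REJECT_SD = 2.5
WINDOWS_S = {"auditory": (0.0, 5.0), "visual": (10.0, 15.0)}
EVOKED_ROIS = ("left_temporal", "right_temporal", "occipital")
WAVELET = "db4"


def wavelet_motion_correct(od: Recording, outlier_threshold: float = 3.0) -> Recording:
    """Suppress motion artefacts by zeroing outlying wavelet detail coefficients.

    Each series is decomposed (db4, maximum depth for its length); detail
    coefficients outside interquartile-range fences of their level
    (``[q1 - thr*IQR, q3 + thr*IQR]``) are set to zero before
    reconstruction.  Spike-like artefacts concentrate in few large
    fine-scale coefficients, so smooth haemodynamics pass through nearly
    unchanged.  Boundary coefficients (signal-extension edges) are never
    zeroed, and levels with fewer than 20 coefficients are left alone —
    their fences are too unstable and spikes do not live at those scales.
    """
    data = od.data.copy()
    n = od.n_samples
    wavelet = pywt.Wavelet(WAVELET)
    level = pywt.dwt_max_level(n, wavelet.dec_len)
    if level < 1:
        warnings.warn("series too short for wavelet decomposition; passing through")
        return od.advanced(od.stage, data, {"step": "wavelet_motion_correct", "skipped": True})
    edge = wavelet.dec_len
    flat = data.reshape(-1, n)
    for k in range(flat.shape[0]):
        coeffs = pywt.wavedec(flat[k], WAVELET, level=level)
        for d in coeffs[1:]:
            if len(d) < 20:
                continue
            interior = d[edge:-edge]
            q1, q3 = np.percentile(interior, [25, 75])
            iqr = q3 - q1
            if iqr == 0:  # degenerate level (e.g. mostly-silent noise-free signal)
                continue
            lo, hi = q1 - outlier_threshold * iqr, q3 + outlier_threshold * iqr
            bad = (interior < lo) | (interior > hi)
            interior[bad] = 0.0
            d[edge:-edge] = interior
        flat[k] = pywt.waverec(coeffs, WAVELET)[:n]
    return od.advanced(
        od.stage, data,
        {"step": "wavelet_motion_correct", "wavelet": WAVELET, "threshold": outlier_threshold},
    )


def bandpass_evoked(
    series: np.ndarray,
    fs_hz: float,
    band: tuple[float, float] = EVOKED_BAND_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Cascaded zero-phase Butterworth high-pass then low-pass filters."""
    lo, hi = band
    if hi >= fs_hz / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs_hz / 2} Hz)")
    sos_hp = sps.butter(order, lo, btype="highpass", fs=fs_hz, output="sos")
    sos_lp = sps.butter(order, hi, btype="lowpass", fs=fs_hz, output="sos")
    n = np.asarray(series).shape[-1]
    # a 0.01 Hz high-pass rings for minutes: pad generously to tame edges
    padlen = int(min(n - 1, 3 * fs_hz / lo))
    out = sps.sosfiltfilt(sos_hp, series, axis=-1, padlen=padlen)
    return sps.sosfiltfilt(sos_lp, out, axis=-1, padlen=padlen)


def bandpass_recording(od: Recording, band=EVOKED_BAND_HZ, order: int = FILTER_ORDER) -> Recording:
    data = bandpass_evoked(od.data, od.sampling_rate_hz, band, order)
    return od.advanced(od.stage, data, {"step": "bandpass", "band_hz": list(band), "order": order})


@dataclass
class EpochSet:
    """Trial x time epochs per channel x chromophore x modality."""

    epochs: dict  # (channel, chromophore, modality) -> (n_trials, n_time)
    kept: dict    # same keys -> boolean array per trial
    times_s: np.ndarray
    missing: list = field(default_factory=list)

    def kept_epochs(self, key) -> np.ndarray:
        return self.epochs[key][self.kept[key]]


def extract_epochs(
    hemo: Recording,
    schedule: StimulusSchedule | None = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> EpochSet:
    """Epoch around stimulus onsets with linear detrend and baseline correction.

    Onsets map to the nearest sample; the window is closed at both ends
    (-5 s and +30 s samples included).  The baseline is -5 s..0 s
    inclusive.  Epochs overrunning the recording edge are dropped with a
    warning.
    """
    schedule = schedule or hemo.schedule
    if schedule is None:
        raise ValueError("no stimulus schedule available")
    fs = hemo.sampling_rate_hz
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    times = np.arange(-pre, post + 1) / fs
    baseline = times <= 0

    epochs: dict = {}
    missing = []
    modalities = sorted({b.modality for b in schedule.blocks})
    for modality in modalities:
        onsets = schedule.onsets(modality)
        idx = np.round(onsets * fs).astype(int)
        valid = (idx - pre >= 0) & (idx + post < hemo.n_samples)
        if not valid.all():
            warnings.warn(f"{(~valid).sum()} {modality} epochs overrun the recording edge; dropped")
        idx = idx[valid]
        if idx.size == 0:
            for cid in hemo.channel_ids:
                for chrom in CHROMOPHORES:
                    missing.append({"channel": cid, "chromophore": chrom, "modality": modality})
            continue
        # gather all epochs at once: (C, 2, n_trials, n_time)
        sample_idx = idx[:, None] + np.arange(-pre, post + 1)[None, :]
        mats = hemo.data[:, :, sample_idx]
        mats = sps.detrend(mats, axis=-1, type="linear")
        mats = mats - mats[..., baseline].mean(axis=-1, keepdims=True)
        for i, cid in enumerate(hemo.channel_ids):
            for j, chrom in enumerate(CHROMOPHORES):
                epochs[(cid, chrom, modality)] = mats[i, j]
    kept = {k: np.ones(v.shape[0], dtype=bool) for k, v in epochs.items()}
    return EpochSet(epochs=epochs, kept=kept, times_s=times, missing=missing)


def reject_epochs(
    epoch_set: EpochSet, sd_threshold: float = REJECT_SD, per_epoch: bool = True
) -> EpochSet:
    """Reject epochs whose maximum exceeds the epoch mean by > threshold SDs.

    Mean and SD are computed over the epoch's own samples by default (the
    literal per-epoch criterion); ``per_epoch=False`` pools mean and SD
    across all epochs of a channel/modality instead.  Flags are updated in
    a new EpochSet; channels/modalities losing every epoch are recorded as
    missing.
    """
    kept = {}
    missing = list(epoch_set.missing)
    for key, mat in epoch_set.epochs.items():
        if per_epoch:
            mu = mat.mean(axis=-1)
            sd = mat.std(axis=-1)
        else:
            mu = np.full(mat.shape[0], mat.mean())
            sd = np.full(mat.shape[0], mat.std())
        flags = ~(mat.max(axis=-1) > mu + sd_threshold * sd)
        kept[key] = flags
        if not flags.any():
            cid, chrom, modality = key
            missing.append({"channel": cid, "chromophore": chrom, "modality": modality,
                            "reason": "all epochs rejected"})
    return EpochSet(epochs=epoch_set.epochs, kept=kept, times_s=epoch_set.times_s, missing=missing)


@dataclass
class EvokedFeatures:
    """Window-mean evoked amplitudes per channel and per ROI."""

    table: pd.DataFrame  # channel, chromophore, modality, value
    roi_means: dict      # (roi, chromophore, modality) -> float

    def channel_value(self, channel: int, chromophore: str, modality: str) -> float:
        sel = self.table[
            (self.table.channel == channel)
            & (self.table.chromophore == chromophore)
            & (self.table.modality == modality)
        ]
        return float(sel.value.iloc[0]) if len(sel) else np.nan


def window_mean_features(epoch_set: EpochSet, montage: Montage) -> EvokedFeatures:
    """Average kept epochs, then average the trace over each modality's window."""
    times = epoch_set.times_s
    rows = []
    for (cid, chrom, modality), mat in epoch_set.epochs.items():
        flags = epoch_set.kept[(cid, chrom, modality)]
        if not flags.any():
            continue
        trace = mat[flags].mean(axis=0)
        lo, hi = WINDOWS_S[modality]
        sel = (times >= lo) & (times <= hi)
        rows.append({"channel": cid, "chromophore": chrom, "modality": modality,
                     "value": float(trace[sel].mean()), "n_epochs": int(flags.sum())})
    table = pd.DataFrame(rows)

    roi_means = {}
    for roi in EVOKED_ROIS:
        members = montage.roi[roi]
        for chrom in CHROMOPHORES:
            for modality in WINDOWS_S:
                if len(table):
                    sel = table[
                        table.channel.isin(members)
                        & (table.chromophore == chrom)
                        & (table.modality == modality)
                    ]
                    roi_means[(roi, chrom, modality)] = (
                        float(sel.value.mean()) if len(sel) else np.nan
                    )
                else:
                    roi_means[(roi, chrom, modality)] = np.nan
    return EvokedFeatures(table=table, roi_means=roi_means)
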