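"""Channel quality control and conversion to hemodynamic signals.

Quality control rejects channels whose acquisition gain exceeds 7
(inadequate detected light) and channels whose scalp coupling index —
the correlation of the two band-passed (0.2–2.5 Hz) wavelength signals,
dominated by the cardiac pulse when optode-scalp contact is good — falls
below 0.75.  Surviving channels are converted to optical density,
resting data are anti-alias resampled to 1 Hz, the superficial systemic
component measured by each long channel's nearest short channel is
regressed out, and concentration changes of oxy- and deoxy-haemoglobin
are obtained from the two-wavelength optical densities via the modified
Beer-Lambert law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import CHROMOPHORES, WAVELENGTHS_NM, Recording

GAIN_THRESHOLD = 7
SCI_THRESHOLD = 0.75
SCI_BAND_HZ = (0.2, 2.5)

#: Extinction coefficients, 1/(M*cm), from a standard compilation of
#: haemoglobin spectra; rows follow WAVELENGTHS_NM, columns (HbO, HbR).
EXTINCTION_DEFAULT = {
    760.0: {"HbO": 1486.5865, "HbR": 3843.707},
    850.0: {"HbO": 2526.391, "HbR": 1798.643},
}
#: Wavelength-specific adult differential pathlength factors.
DPF_DEFAULT = {760.0: 6.4, 850.0: 5.75}


@dataclass(frozen=True)
class OpticsConstants:
    """Constants of the modified Beer-Lambert relation."""

    extinction: dict = field(default_factory=lambda: EXTINCTION_DEFAULT)
    dpf: dict = field(default_factory=lambda: DPF_DEFAULT)

    def matrix(self, separation_cm: float) -> np.ndarray:
        """2x2 map from (HbO, HbR) in molar to optical density per wavelength."""
        m = np.array(
            [
                [self.extinction[wl][ch] * self.dpf[wl] * separation_cm for ch in CHROMOPHORES]
                for wl in WAVELENGTHS_NM
            ]
        )
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("extinction/DPF configuration yields a singular system")
        return m


@dataclass
class QcReport:
    table: pd.DataFrame  # columns: channel, gain, sci, kept, reject_reason

    @property
    def kept_ids(self) -> list[int]:
        return list(self.table.loc[self.table.kept, "channel"])

    @property
    def rejected_ids(self) -> list[int]:
        return list(self.table.loc[~self.table.kept, "channel"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def scalp_coupling_index(raw: Recording, band=SCI_BAND_HZ) -> dict[int, float]:
    """Correlation of the two band-passed wavelength signals, per channel."""
    if raw.stage != "intensity":
        raise ValueError("SCI is computed on raw intensity recordings")
    if raw.n_samples / raw.sampling_rate_hz <= 10:
        raise ValueError("SCI needs more than 10 s of data")
    sos = signal.butter(4, band, btype="bandpass", fs=raw.sampling_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.data, axis=-1)
    sci = {}
    for i, cid in enumerate(raw.channel_ids):
        x, y = filtered[i, 0], filtered[i, 1]
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            warnings.warn(f"channel {cid}: constant band-passed signal; SCI set to 0")
            sci[cid] = 0.0
        else:
            sci[cid] = float(np.corrcoef(x, y)[0, 1])
    return sci


def apply_qc(
    raw: Recording,
    gain_threshold: int = GAIN_THRESHOLD,
    sci_threshold: float = SCI_THRESHOLD,
) -> tuple[Recording, QcReport]:
    """Reject channels on gain, then on scalp coupling index."""
    if raw.montage is None:
        raise ValueError("QC needs a montage with per-channel gains")
    sci = scalp_coupling_index(raw)
    rows = []
    for cid in raw.channel_ids:
        gain = raw.montage.channel(cid).gain
        if gain > gain_threshold:
            reason, kept = "gain", False
        elif sci[cid] < sci_threshold:
            reason, kept = "sci", False
        else:
            reason, kept = "none", True
        rows.append({"channel": cid, "gain": gain, "sci": sci[cid], "kept": kept, "reject_reason": reason})
    report = QcReport(pd.DataFrame(rows))
    kept = report.kept_ids
    if not kept:
        raise RuntimeError(
            f"all channels rejected (gain > {gain_threshold} or SCI < {sci_threshold})"
        )
    out = raw.subset(kept)
    out.provenance = raw.provenance + [
        {"step": "qc", "gain_threshold": gain_threshold, "sci_threshold": sci_threshold,
         "rejected": report.rejected_ids}
    ]
    return out, report


def intensity_to_od(raw: Recording) -> Recording:
    """Optical density change: -log10 of intensity over its temporal mean."""
    if raw.stage != "intensity":
        raise ValueError("input must be an intensity recording")
    bad = np.argwhere(raw.data <= 0)
    if bad.size:
        i, j, t = bad[0]
        raise ValueError(
            f"non-positive intensity at channel {raw.channel_ids[i]}, "
            f"band {raw.bands[j]}, sample {t}"
        )
    ref = raw.data.mean(axis=-1, keepdims=True)
    od = -np.log10(raw.data / ref)
    return raw.advanced("od", od, {"step": "intensity_to_od", "reference": "temporal mean"})


def downsample_resting(od: Recording, target_hz: float = 1.0) -> Recording:
    """Anti-aliased polyphase resampling of resting-state optical density."""
    if target_hz > od.sampling_rate_hz:
        raise ValueError("target rate exceeds original sampling rate")
    from fractions import Fraction

    frac = Fraction(target_hz / od.sampling_rate_hz).limit_denominator(10000)
    data = signal.resample_poly(
        od.data, frac.numerator, frac.denominator, axis=-1, padtype="line"
    )
    out = od.advanced("od", data, {"step": "downsample", "target_hz": target_hz})
    out.sampling_rate_hz = target_hz
    return out


def short_channel_correct(od: Recording) -> Recording:
    """Subtract the least-squares scaled nearest short channel from each long channel.

    The scaling fraction is estimated per long channel and per wavelength
    by ordinary least squares of the short-channel series onto the long
    one, removing scalp-level and global systemic fluctuations.  If a
    region's short channel was rejected by QC the nearest surviving short
    channel is used; with no surviving short channels the recording
    passes through unchanged with a warning.
    """
    if od.stage != "od":
        raise ValueError("short-channel correction operates on optical density")
    montage = od.montage
    if montage is None:
        raise ValueError("recording has no montage")
    present = set(od.channel_ids)
    surviving_shorts = [s for s in montage.short_ids if s in present]
    if not surviving_shorts:
        warnings.warn("no surviving short channels; skipping superficial correction")
        return od

    data = od.data.copy()
    betas = {}
    for i, cid in enumerate(od.channel_ids):
        if montage.channel(cid).is_short:
            continue
        short_id = montage.nearest_short.get(cid)
        if short_id not in present:
            short_id = surviving_shorts[0]  # fallback: any surviving short
        s_idx = od.index_of(short_id)
        for j in range(len(od.bands)):
            s = od.data[s_idx, j] - od.data[s_idx, j].mean()
            l = od.data[i, j] - od.data[i, j].mean()
            denom = float(s @ s)
            if denom == 0:
                warnings.warn(f"zero-variance short channel {short_id}; skipping channel {cid}")
                continue
            beta = float(s @ l) / denom
            data[i, j] = od.data[i, j] - beta * od.data[s_idx, j]
            betas[f"ch{cid}_{od.bands[j]}"] = beta
    return od.advanced("od", data, {"step": "short_channel_correction", "beta": betas})


def beer_lambert(od: Recording, constants: OpticsConstants | None = None) -> Recording:
    """Solve the modified Beer-Lambert system for (HbO, HbR), in micromolar."""
    if od.stage != "od":
        raise ValueError("input must be an optical-density recording")
    constants = constants or OpticsConstants()
    hemo = np.empty_like(od.data)
    for i, cid in enumerate(od.channel_ids):
        sep_cm = (od.montage.channel(cid).separation_mm / 10.0) if od.montage else 3.0
        m = constants.matrix(sep_cm)
        hemo[i] = np.linalg.solve(m, od.data[i]) * 1e6  # molar -> micromolar
    return od.advanced("hemo", hemo, {"step": "beer_lambert"})


def forward_beer_lambert(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    separation_cm: float,
    constants: OpticsConstants | None = None,
) -> np.ndarray:
    """Forward map from micromolar (HbO, HbR) to optical density per wavelength."""
    constants = constants or OpticsConstants()
    m = constants.matrix(separation_cm)
    conc = np.vstack([hbo_um, hbr_um]) * 1e-6
    return m @ conc
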