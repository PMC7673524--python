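"""Multi-channel recording container and on-disk formats.

A :class:`Recording` holds one subject's multi-channel time series at a
given processing stage:

``intensity``
    raw detected light intensity, one series per channel per wavelength
    (760 and 850 nm);
``od``
    optical density changes, same layout;
``hemo``
    hemodynamic concentration changes, one series per channel per
    chromophore (HbO, HbR), in micromolar.

Data are stored as a dense ``(n_channels, n_bands, n_samples)`` array.
On disk, recordings use an HDF5 layout following SNIRF conventions
(data block + channel table + stimulus table) with a wide-CSV fallback.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .montage import Channel, Montage
from .schedule import StimulusBlock, StimulusSchedule

WAVELENGTHS_NM = (760.0, 850.0)
CHROMOPHORES = ("HbO", "HbR")

_STAGE_BANDS = {"intensity": WAVELENGTHS_NM, "od": WAVELENGTHS_NM, "hemo": CHROMOPHORES}
_STAGE_ORDER = ("intensity", "od", "hemo")


@dataclass
class Recording:
    stage: str
    channel_ids: tuple[int, ...]
    bands: tuple
    data: np.ndarray  # (n_channels, n_bands, n_samples)
    sampling_rate_hz: float
    montage: Montage | None = None
    schedule: StimulusSchedule | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_BANDS:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[:2] != (len(self.channel_ids), len(self.bands)):
            raise ValueError("data shape inconsistent with channel_ids/bands")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def index_of(self, channel_id: int) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"channel {channel_id} not in recording") from None

    def get(self, channel_id: int, band) -> np.ndarray:
        return self.data[self.index_of(channel_id), self.bands.index(band)]

    def advanced(self, stage: str, data: np.ndarray, note: dict | None = None) -> "Recording":
        """Return a copy advanced to ``stage`` with new data.

        Stage transitions must follow intensity -> od -> hemo (a stage may
        also map onto itself, e.g. filtering optical density).
        """
        if _STAGE_ORDER.index(stage) < _STAGE_ORDER.index(self.stage):
            raise ValueError(f"cannot move from stage {self.stage!r} back to {stage!r}")
        return replace(
            self,
            stage=stage,
            bands=_STAGE_BANDS[stage],
            data=np.asarray(data, dtype=float),
            provenance=self.provenance + ([note] if note else []),
        )

    def subset(self, channel_ids) -> "Recording":
        keep = [self.index_of(c) for c in channel_ids]
        return replace(self, channel_ids=tuple(channel_ids), data=self.data[keep])

    def slice_time(self, sl: slice) -> "Recording":
        return replace(self, data=self.data[:, :, sl])

    # ---------------------------------------------------------------- IO

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["stage"] = self.stage
            f.attrs["sampling_rate_hz"] = self.sampling_rate_hz
            f.create_dataset("data", data=self.data)
            f.create_dataset("channel_ids", data=np.array(self.channel_ids))
            f.create_dataset("bands", data=np.array([str(b) for b in self.bands], dtype="S"))
            if self.montage is not None:
                f.attrs["montage"] = montage_to_json(self.montage)
            if self.schedule is not None:
                f.attrs["schedule"] = schedule_to_json(self.schedule)
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            stage = f.attrs["stage"]
            bands = tuple(b.decode() for b in f["bands"][()])
            if stage in ("intensity", "od"):
                bands = tuple(float(b) for b in bands)
            return cls(
                stage=stage,
                channel_ids=tuple(int(c) for c in f["channel_ids"][()]),
                bands=bands,
                data=f["data"][()],
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                montage=montage_from_json(f.attrs["montage"]) if "montage" in f.attrs else None,
                schedule=schedule_from_json(f.attrs["schedule"]) if "schedule" in f.attrs else None,
                provenance=json.loads(f.attrs.get("provenance", "[]")),
            )

    def to_csv(self, path) -> None:
        """Wide CSV fallback: one column per channel-band series."""
        cols = {
            f"ch{cid}_{band}": self.data[i, j]
            for i, cid in enumerate(self.channel_ids)
            for j, band in enumerate(self.bands)
        }
        pd.DataFrame(cols).to_csv(path, index=False)


# ------------------------------------------------------- JSON sidecars


def montage_to_json(montage: Montage) -> str:
    return json.dumps(
        {
            "channels": [dataclasses.asdict(ch) for ch in montage.channels],
            "seeds": {k: sorted(v) for k, v in montage.seeds.items()},
            "roi": {k: sorted(v) for k, v in montage.roi.items()},
            "nearest_short": {str(k): v for k, v in montage.nearest_short.items()},
        }
    )


def montage_from_json(text: str) -> Montage:
    d = json.loads(text)
    return Montage(
        channels=tuple(Channel(**ch) for ch in d["channels"]),
        seeds={k: frozenset(v) for k, v in d["seeds"].items()},
        roi={k: frozenset(v) for k, v in d["roi"].items()},
        nearest_short={int(k): v for k, v in d["nearest_short"].items()},
    )


def schedule_to_json(schedule: StimulusSchedule) -> str:
    return json.dumps(
        {
            "periods": list(schedule.periods),
            "blocks": [dataclasses.asdict(b) for b in schedule.blocks],
            "sampling_rate_hz": schedule.sampling_rate_hz,
            "nsi_values": list(schedule.nsi_values),
        }
    )


def schedule_from_json(text: str) -> StimulusSchedule:
    d = json.loads(text)
    return StimulusSchedule(
        periods=tuple((k, float(v)) for k, v in d["periods"]),
        blocks=tuple(StimulusBlock(**b) for b in d["blocks"]),
        sampling_rate_hz=float(d["sampling_rate_hz"]),
        nsi_values=tuple(d["nsi_values"]),
    )
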