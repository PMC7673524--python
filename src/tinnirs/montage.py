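"""Optode montage: channel table, seeds, regions of interest.

The default montage mirrors a 16-source / 16-detector whole-head layout
covering frontal, temporal and occipital cortex: 36 *long* channels at
30 mm source-detector separation (cortex-sensitive) and one *short*
channel at 11 mm in each of the four covered regions (scalp-sensitive,
used for superficial systemic regression).  Channel numbering, the
temporal-channel anatomical labels, the bilateral temporal seed pairs
and the frontal/occipital connectivity ROIs are fixed montage metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

LONG_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 11.0

#: Anatomical labels of the 16 temporal long channels (8 per side).
TEMPORAL_REGIONS = {
    9: "Superior temporal gyrus",
    10: "Superior temporal gyrus",
    11: "Supramarginal gyrus",
    13: "Middle temporal gyrus",
    14: "Middle temporal gyrus",
    16: "Inferior temporal gyrus",
    17: "Angular gyrus",
    18: "Middle temporal gyrus",
    30: "Superior temporal gyrus",
    31: "Heschl's gyrus",
    32: "Supramarginal gyrus",
    34: "Middle temporal gyrus",
    35: "Superior temporal gyrus",
    37: "Middle temporal gyrus",
    38: "Angular gyrus",
    39: "Middle temporal gyrus",
}

FRONTAL_ROI = (1, 3, 4, 5, 6, 7, 8, 26, 27, 28, 29)
OCCIPITAL_ROI = (20, 21, 23, 24, 25, 41, 42)
LEFT_TEMPORAL_ROI = (9, 10, 11, 13, 14, 16, 17, 18)
RIGHT_TEMPORAL_ROI = (30, 31, 32, 34, 35, 37, 38, 39)
SEED_LEFT = (9, 10)
SEED_RIGHT = (30, 31)

# Frontal / occipital labels (anatomy covered per the montage description;
# the per-channel assignment outside the temporal lists is montage metadata).
_FRONTAL_REGIONS = {
    1: "Superior frontal gyrus",
    3: "Superior frontal gyrus, medial",
    4: "Superior frontal gyrus, medial orbital",
    5: "Middle frontal gyrus",
    6: "Superior frontal gyrus",
    7: "Middle frontal gyrus",
    8: "Superior frontal gyrus, medial",
    26: "Superior frontal gyrus",
    27: "Superior frontal gyrus, medial",
    28: "Middle frontal gyrus",
    29: "Superior frontal gyrus, medial orbital",
}
_OCCIPITAL_REGIONS = {
    20: "Cuneus",
    21: "Superior occipital gyrus",
    23: "Cuneus",
    24: "Superior occipital gyrus",
    25: "Cuneus",
    41: "Cuneus",
    42: "Superior occipital gyrus",
}
# Two long channels outside every ROI (parietal coverage between the pads).
_OTHER_REGIONS = {12: "Postcentral gyrus", 33: "Postcentral gyrus"}

#: Short channels: one per covered region, keyed by id -> region group.
SHORT_CHANNELS = {2: "frontal", 15: "left_temporal", 36: "right_temporal", 22: "occipital"}

_LEFT_IDS = set(range(1, 26)) - {2, 22}
_RIGHT_IDS = set(range(26, 43)) - {36}


@dataclass(frozen=True)
class Channel:
    """A single source-detector pair."""

    id: int
    source: int
    detector: int
    separation_mm: float
    region: str
    side: str  # left | right | midline
    gain: int = 1

    def __post_init__(self) -> None:
        if self.separation_mm not in (LONG_SEPARATION_MM, SHORT_SEPARATION_MM):
            raise ValueError(f"separation must be 30 or 11 mm, got {self.separation_mm}")
        if not 1 <= self.gain <= 8:
            raise ValueError(f"gain must be in 1..8, got {self.gain}")

    @property
    def is_short(self) -> bool:
        return self.separation_mm == SHORT_SEPARATION_MM


@dataclass(frozen=True)
class Montage:
    """Channel table plus seed and ROI definitions."""

    channels: tuple[Channel, ...]
    seeds: dict[str, frozenset[int]]
    roi: dict[str, frozenset[int]]
    nearest_short: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [ch.id for ch in self.channels]
        if len(ids) != len(set(ids)):
            raise ValueError("channel ids must be unique")

    def channel(self, channel_id: int) -> Channel:
        return self._by_id[channel_id]

    @property
    def _by_id(self) -> dict[int, Channel]:
        return {ch.id: ch for ch in self.channels}

    @property
    def long_ids(self) -> tuple[int, ...]:
        return tuple(ch.id for ch in self.channels if not ch.is_short)

    @property
    def short_ids(self) -> tuple[int, ...]:
        return tuple(ch.id for ch in self.channels if ch.is_short)

    def with_gains(self, gains: dict[int, int]) -> "Montage":
        """Return a copy with per-channel gains replaced."""
        new = tuple(
            replace(ch, gain=gains.get(ch.id, ch.gain)) for ch in self.channels
        )
        return replace(self, channels=new)


def _region_group(channel_id: int) -> str:
    if channel_id in _FRONTAL_REGIONS or channel_id == 2:
        return "frontal"
    if channel_id in LEFT_TEMPORAL_ROI or channel_id in (12, 15):
        return "left_temporal"
    if channel_id in RIGHT_TEMPORAL_ROI or channel_id in (33, 36):
        return "right_temporal"
    return "occipital"


def build_montage(config: str | dict = "default") -> Montage:
    """Build a named montage variant.

    Only the ``"default"`` variant (36 long + 4 short channels) is defined.
    """
    variant = config if isinstance(config, str) else config.get("variant", "default")
    if variant != "default":
        raise ValueError(f"unknown montage variant {variant!r}; only 'default' is defined")

    regions: dict[int, str] = {}
    regions.update(_FRONTAL_REGIONS)
    regions.update(TEMPORAL_REGIONS)
    regions.update(_OCCIPITAL_REGIONS)
    regions.update(_OTHER_REGIONS)

    channels = []
    all_ids = sorted(set(regions) | set(SHORT_CHANNELS))
    for i, cid in enumerate(all_ids):
        short = cid in SHORT_CHANNELS
        side = "left" if cid in _LEFT_IDS else ("right" if cid in _RIGHT_IDS else "midline")
        region = regions.get(cid, f"Superficial — {SHORT_CHANNELS.get(cid, '?')}")
        # Source/detector indices cycle through the 16 available optodes of
        # each kind; positions themselves are not modelled.
        channels.append(
            Channel(
                id=cid,
                source=i % 16 + 1,
                detector=(i // 3 + i) % 16 + 1,
                separation_mm=SHORT_SEPARATION_MM if short else LONG_SEPARATION_MM,
                region=region,
                side=side,
            )
        )

    nearest_short = {}
    short_by_group = {group: cid for cid, group in SHORT_CHANNELS.items()}
    for ch in channels:
        if not ch.is_short:
            nearest_short[ch.id] = short_by_group[_region_group(ch.id)]

    montage = Montage(
        channels=tuple(channels),
        seeds={"left": frozenset(SEED_LEFT), "right": frozenset(SEED_RIGHT)},
        roi={
            "frontal": frozenset(FRONTAL_ROI),
            "occipital": frozenset(OCCIPITAL_ROI),
            "left_temporal": frozenset(LEFT_TEMPORAL_ROI),
            "right_temporal": frozenset(RIGHT_TEMPORAL_ROI),
        },
        nearest_short=nearest_short,
    )
    assert len(montage.long_ids) == 36 and len(montage.short_ids) == 4
    return montage
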