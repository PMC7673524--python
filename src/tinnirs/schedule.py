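"""Block-design stimulus schedule.

The recording session has three contiguous recording periods: a 360 s
eyes-closed resting-state period, then two stimulus periods delivering
15 s auditory (pink noise) and visual (reversing checkerboard) blocks.
Six blocks of each modality are presented in period 2 and four of each
in period 3 (10 per modality in total), in randomised order with never
more than two consecutive blocks of the same modality, separated by
non-stimulus intervals of 20 or 25 s.  Data are sampled at 7.8125 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLING_RATE_HZ = 7.8125
BLOCK_DURATION_S = 15.0
NSI_VALUES_S = (20.0, 25.0)
RESTING_DURATION_S = 360.0
_LEAD_IN_S = 20.0
_TRAIL_S = 35.0  # leaves room for the -5..30 s epoch of the last block


@dataclass(frozen=True)
class StimulusBlock:
    modality: str  # auditory | visual
    onset_s: float
    duration_s: float = BLOCK_DURATION_S


@dataclass(frozen=True)
class StimulusSchedule:
    periods: tuple[tuple[str, float], ...]  # (kind, duration_s)
    blocks: tuple[StimulusBlock, ...]
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    nsi_values: tuple[float, ...] = NSI_VALUES_S

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.periods)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    def onsets(self, modality: str) -> np.ndarray:
        return np.array([b.onset_s for b in self.blocks if b.modality == modality])

    def period_slice(self, index: int) -> slice:
        """Sample slice of the index-th recording period."""
        starts = np.cumsum([0.0] + [d for _, d in self.periods])
        fs = self.sampling_rate_hz
        return slice(int(round(starts[index] * fs)), int(round(starts[index + 1] * fs)))

    @property
    def resting_slice(self) -> slice:
        for i, (kind, _) in enumerate(self.periods):
            if kind == "resting":
                return self.period_slice(i)
        raise ValueError("schedule has no resting period")

    def boxcar(self, modality: str) -> np.ndarray:
        """0/1 stimulus indicator sampled on the recording grid."""
        t = np.arange(self.n_samples) / self.sampling_rate_hz
        box = np.zeros(self.n_samples)
        for b in self.blocks:
            if b.modality == modality:
                box[(t >= b.onset_s) & (t < b.onset_s + b.duration_s)] = 1.0
        return box


def _max_run(seq: list[str]) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def _randomised_order(
    n_each: int, rng: np.random.Generator, tail: list[str] | None = None
) -> list[str]:
    """Shuffled modality order with max run length 2, also counting the
    tail of the preceding period."""
    seq = ["auditory"] * n_each + ["visual"] * n_each
    for _ in range(1000):
        rng.shuffle(seq)
        if _max_run((tail or []) + seq) <= 2:
            return list(seq)
    raise RuntimeError("could not draw a block order with max run length 2")


def build_schedule(config: dict | None = None, rng: np.random.Generator | None = None) -> StimulusSchedule:
    """Draw a randomised session schedule.

    ``config`` may override ``include_evoked`` (set False for resting-only
    simulations) and ``resting_duration_s``.  Deterministic given the seed
    of ``rng``.
    """
    config = config or {}
    rng = rng if rng is not None else np.random.default_rng(0)
    resting = float(config.get("resting_duration_s", RESTING_DURATION_S))
    periods: list[tuple[str, float]] = [("resting", resting)]
    blocks: list[StimulusBlock] = []

    if config.get("include_evoked", True):
        t0 = resting
        tail: list[str] = []
        for n_each in (6, 4):
            order = _randomised_order(n_each, rng, tail=tail)
            tail = order[-2:]
            t = t0 + _LEAD_IN_S
            for i, modality in enumerate(order):
                blocks.append(StimulusBlock(modality=modality, onset_s=t))
                t += BLOCK_DURATION_S
                if i < len(order) - 1:
                    t += float(rng.choice(NSI_VALUES_S))
            period_duration = (t + _TRAIL_S) - t0
            periods.append(("stimulus", period_duration))
            t0 += period_duration

    return StimulusSchedule(periods=tuple(periods), blocks=tuple(blocks))
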