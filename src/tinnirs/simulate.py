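"""Synthetic fNIRS cohort generator with known ground truth.

Each simulated subject is built forward through the physics that the
preprocessing chain inverts:

1. *Cortical* HbO/HbR per channel (micromolar): a canonical
   double-gamma haemodynamic response convolved with the stimulus
   boxcar (auditory blocks drive temporal channels, visual blocks drive
   occipital channels), plus latent resting-state network signals whose
   sample correlations with the bilateral temporal seeds are imposed
   exactly at the requested targets.
2. *Physiology*: a per-channel cardiac sinusoid (the signal the scalp
   coupling index looks for) and a shared superficial systemic signal
   (slow drift + respiration + Mayer wave) added at full amplitude to
   each short channel and at ``superficial_frac`` to every long channel.
3. *Noise*: per-channel AR(1) concentration noise plus white
   per-wavelength optical-density measurement noise.
4. Concentrations map to optical density through the same modified
   Beer-Lambert forward relation used in preprocessing, and to detected
   intensity as ``I = I0 * 10**(-dOD)`` with ``I0 = 1``.

Bad channels get acquisition gain 8 (good channels draw 1–7) and no
cardiac component, so QC rejects them on the gain criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import signal as sps
from scipy import stats

from .montage import Montage, build_montage
from .preprocess import OpticsConstants, forward_beer_lambert
from .recording import CHROMOPHORES, WAVELENGTHS_NM, Recording
from .schedule import StimulusSchedule, build_schedule

#: modality -> montage ROIs whose channels respond to it
EVOKED_TARGETS = {
    "auditory": ("left_temporal", "right_temporal"),
    "visual": ("occipital",),
}

_LATENT_NODES = ("seed_left", "seed_right", "frontal", "occipital")


def default_connectivity(base: float = 0.15) -> dict:
    """Flat connectivity targets for all seed x ROI x chromophore pairs."""
    return {
        (side, roi, ch): base
        for side in ("left", "right")
        for roi in ("frontal", "occipital")
        for ch in CHROMOPHORES
    }


def default_evoked_amp(hbo_peak: float = 0.4) -> dict:
    """Peak response amplitudes (micromolar); HbR inversely coupled at -1/3."""
    amp = {}
    for roi in ("left_temporal", "right_temporal", "occipital"):
        amp[(roi, "HbO")] = hbo_peak
        amp[(roi, "HbR")] = -hbo_peak / 3.0
    return amp


@dataclass
class SubjectSpec:
    """Ground-truth generating parameters for one subject."""

    group: str = "control"  # control | tinnitus
    thi: float = 0.0
    loudness: float = 0.0
    annoyance: float = 0.0
    duration_years: float = 0.0
    age: float = 45.0
    hearing_4k: float = 25.0
    hearing_8k: float = 25.0
    evoked_amp: dict = field(default_factory=default_evoked_amp)
    connectivity: dict = field(default_factory=default_connectivity)
    seed_seed_rho: float = 0.3
    frontal_occipital_rho: float = 0.1
    cardiac_amp: float = 0.2
    cardiac_hz: float = 1.1
    resp_amp: float = 0.2
    resp_hz: float = 0.25
    mayer_amp: float = 0.25
    mayer_hz: float = 0.1
    superficial_frac: float = 0.5
    superficial_sd: float = 1.2
    hbr_systemic_frac: float = 0.3
    resting_sd: float = 0.5
    resting_ar: float = 0.95
    ar_coeff: float = 0.4
    noise_sd: float = 0.2
    od_noise_sd: float = 5e-7
    bad_channels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.thi <= 100:
            raise ValueError("THI must be in 0..100")
        if any(abs(r) >= 1 for r in self.connectivity.values()):
            raise ValueError("connectivity targets must satisfy |rho| < 1")

    @classmethod
    def silent(cls, **overrides) -> "SubjectSpec":
        """A spec with every signal source switched off."""
        quiet = dict(
            evoked_amp={k: 0.0 for k in default_evoked_amp()},
            cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
            superficial_sd=0.0, superficial_frac=0.0,
            resting_sd=0.0, noise_sd=0.0, od_noise_sd=0.0,
        )
        quiet.update(overrides)
        return cls(**quiet)


@dataclass
class GroundTruth:
    """Noise-free cortical signals and generating parameters."""

    channel_ids: tuple[int, ...]
    clean: np.ndarray   # (C, 2, T) cortical HbO/HbR, micromolar
    evoked: np.ndarray  # (C, 2, T) evoked component only
    connectivity: dict
    spec: SubjectSpec

    def clean_series(self, channel_id: int, chromophore: str) -> np.ndarray:
        i = self.channel_ids.index(channel_id)
        return self.clean[i, CHROMOPHORES.index(chromophore)]

    def evoked_series(self, channel_id: int, chromophore: str) -> np.ndarray:
        i = self.channel_ids.index(channel_id)
        return self.evoked[i, CHROMOPHORES.index(chromophore)]


def double_gamma_hrf(fs_hz: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic impulse response (peak ~6 s,
    undershoot ~16 s), normalised to unit peak."""
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    peak = stats.gamma.pdf(t, a=7.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=17.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def block_response(schedule: StimulusSchedule, modality: str) -> np.ndarray:
    """Evoked trace for a modality: boxcar * HRF, unit single-block peak."""
    fs = schedule.sampling_rate_hz
    h = double_gamma_hrf(fs)
    single = np.zeros(int(60 * fs))
    single[: int(15 * fs)] = 1.0
    norm = np.convolve(single, h)[: len(single)].max()
    box = schedule.boxcar(modality)
    return np.convolve(box, h)[: len(box)] / norm


def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter rows, scaled to preserve the innovation variance."""
    if phi == 0:
        return innovations
    out = sps.lfilter([1.0], [1.0, -phi], innovations, axis=-1)
    return out * np.sqrt(1.0 - phi**2)


def _impose_correlation(series: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Linearly transform rows so their *sample* correlation equals target."""
    x = series - series.mean(axis=-1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    try:
        l_emp = np.linalg.cholesky(cov)
        l_tgt = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "connectivity targets do not form a positive-definite correlation "
            f"matrix: {np.array2string(target, precision=3)}"
        ) from err
    white = np.linalg.solve(l_emp, x)
    return l_tgt @ white


def _latent_target_matrix(spec: SubjectSpec, chromophore: str) -> np.ndarray:
    r = np.eye(len(_LATENT_NODES))
    idx = {n: i for i, n in enumerate(_LATENT_NODES)}
    def put(a, b, v):
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    put("seed_left", "seed_right", spec.seed_seed_rho)
    put("frontal", "occipital", spec.frontal_occipital_rho)
    for side in ("left", "right"):
        for roi in ("frontal", "occipital"):
            put(f"seed_{side}", roi, spec.connectivity[(side, roi, chromophore)])
    return r


def _resting_latents(spec: SubjectSpec, n: int, chromophore: str,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent network signals with exactly the target sample correlations."""
    sd = spec.resting_sd if chromophore == "HbO" else spec.resting_sd / 3.0
    if sd == 0:
        return {node: np.zeros(n) for node in _LATENT_NODES}
    target = _latent_target_matrix(spec, chromophore)
    raw = _ar1(rng.standard_normal((len(_LATENT_NODES), n)), spec.resting_ar)
    mixed = _impose_correlation(raw, target)
    mixed *= sd / mixed.std(axis=-1, keepdims=True)
    return dict(zip(_LATENT_NODES, mixed))


def _channel_latent_node(montage: Montage, channel_id: int) -> str | None:
    if channel_id in montage.seeds["left"]:
        return "seed_left"
    if channel_id in montage.seeds["right"]:
        return "seed_right"
    if channel_id in montage.roi["frontal"]:
        return "frontal"
    if channel_id in montage.roi["occipital"]:
        return "occipital"
    return None


def simulate_subject(
    spec: SubjectSpec,
    montage: Montage,
    schedule: StimulusSchedule,
    rng: np.random.Generator,
    constants: OpticsConstants | None = None,
) -> tuple[Recording, GroundTruth]:
    """Forward-simulate one subject's raw dual-wavelength intensities."""
    constants = constants or OpticsConstants()
    fs = schedule.sampling_rate_hz
    n = schedule.n_samples
    t = np.arange(n) / fs
    ids = montage.long_ids + montage.short_ids
    n_ch = len(ids)

    # -- evoked cortical component
    evoked = np.zeros((n_ch, 2, n))
    for modality, rois in EVOKED_TARGETS.items():
        if not schedule.onsets(modality).size:
            continue
        trace = block_response(schedule, modality)
        for roi in rois:
            for cid in montage.roi[roi]:
                i = ids.index(cid)
                for j, ch in enumerate(CHROMOPHORES):
                    evoked[i, j] += spec.evoked_amp.get((roi, ch), 0.0) * trace

    # -- resting latent network + independent latents elsewhere
    resting = np.zeros((n_ch, 2, n))
    for j, ch in enumerate(CHROMOPHORES):
        latents = _resting_latents(spec, n, ch, rng)
        sd = spec.resting_sd if ch == "HbO" else spec.resting_sd / 3.0
        for i, cid in enumerate(ids):
            if montage.channel(cid).is_short:
                continue
            node = _channel_latent_node(montage, cid)
            if node is not None:
                resting[i, j] = latents[node]
            elif sd > 0:
                own = _ar1(rng.standard_normal(n), spec.resting_ar)
                resting[i, j] = own * sd / own.std()

    clean = evoked + resting

    # -- physiology: cardiac per channel, shared superficial systemic signal
    cardiac_hz = spec.cardiac_hz + rng.normal(0.0, 0.05)
    resp_hz = spec.resp_hz + rng.normal(0.0, 0.02)
    mayer_hz = spec.mayer_hz + rng.normal(0.0, 0.01)
    superficial = np.zeros(n)
    if spec.superficial_sd > 0:
        drift = _ar1(rng.standard_normal(n), 0.995)
        superficial = drift * spec.superficial_sd / drift.std()
    superficial = (
        superficial
        + spec.resp_amp * np.sin(2 * np.pi * resp_hz * t + rng.uniform(0, 2 * np.pi))
        + spec.mayer_amp * np.sin(2 * np.pi * mayer_hz * t + rng.uniform(0, 2 * np.pi))
    )

    measured = clean.copy()
    fracs = np.array(
        [1.0 if montage.channel(cid).is_short else spec.superficial_frac for cid in ids]
    )
    measured[:, 0] += fracs[:, None] * superficial
    measured[:, 1] += fracs[:, None] * spec.hbr_systemic_frac * superficial
    if spec.cardiac_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        good = np.array([cid not in spec.bad_channels for cid in ids], dtype=float)
        pulse = (
            spec.cardiac_amp
            * good[:, None]
            * np.sin(2 * np.pi * cardiac_hz * t[None, :] + phases[:, None])
        )
        measured[:, 0] += pulse
        measured[:, 1] += spec.hbr_systemic_frac * pulse

    if spec.noise_sd > 0:
        noise = _ar1(rng.standard_normal((n_ch, 2, n)), spec.ar_coeff)
        noise /= noise.std(axis=-1, keepdims=True)
        # HbR fluctuations run ~1/3 the magnitude of HbO, like the latents
        measured[:, 0] += spec.noise_sd * noise[:, 0]
        measured[:, 1] += spec.noise_sd / 3.0 * noise[:, 1]

    # -- forward optics: concentrations -> optical density -> intensity
    gains = {
        cid: 8 if cid in spec.bad_channels else int(rng.integers(1, 8)) for cid in ids
    }
    gained_montage = montage.with_gains(gains)
    mats = np.stack(
        [constants.matrix(montage.channel(cid).separation_mm / 10.0) for cid in ids]
    )
    od = np.einsum("cwk,ckt->cwt", mats, measured * 1e-6)
    if spec.od_noise_sd > 0:
        od += rng.normal(0.0, spec.od_noise_sd, size=od.shape)
    intensity = 10.0 ** (-od)

    recording = Recording(
        stage="intensity",
        channel_ids=ids,
        bands=WAVELENGTHS_NM,
        data=intensity,
        sampling_rate_hz=fs,
        montage=gained_montage,
        schedule=schedule,
        provenance=[{"step": "simulate", "group": spec.group}],
    )
    truth = GroundTruth(
        channel_ids=ids,
        clean=clean,
        evoked=evoked,
        connectivity=dict(spec.connectivity),
        spec=spec,
    )
    return recording, truth


# ------------------------------------------------------------- cohorts


@dataclass
class CohortConfig:
    """Group sizes, effect sizes and covariate distributions for a cohort.

    Default effect directions follow the study's group contrasts: higher
    temporal-frontal HbO and right temporal-occipital HbR connectivity
    in tinnitus, lower auditory and visual evoked amplitudes in
    tinnitus, occipital HbR connectivity increasing with loudness and
    frontal HbO connectivity increasing with tinnitus duration.
    """

    n_control: int = 18
    n_tinnitus: int = 25
    severity_counts: tuple[int, int] = (18, 7)  # slight/mild (THI<=36), moderate/severe
    bad_channel_rate: float = 0.13
    connectivity_base: float = 0.15
    d_frontal_hbo_right: float = 0.20
    d_frontal_hbo_left: float = 0.15
    d_occipital_hbr_right: float = 0.20
    loudness_slope_occ_hbr: float = 0.036
    duration_slope_frontal_hbo: float = 0.021
    d_severity_conn: float = 0.0  # extra right-seed HbR connectivity, moderate/severe only
    evoked_hbo_peak_control: float = 0.4
    evoked_reduction_tinnitus: float = 0.15
    schedule: dict = field(default_factory=dict)
    spec_overrides: dict = field(default_factory=dict)


@dataclass
class SimulatedSubject:
    subject_id: str
    spec: SubjectSpec
    recording: Recording
    truth: GroundTruth


def _clip_rho(r: float) -> float:
    return float(np.clip(r, -0.9, 0.9))


_ID_CACHE: dict[str, np.ndarray] = {}


def _default_channel_ids() -> np.ndarray:
    if "ids" not in _ID_CACHE:
        m = build_montage()
        _ID_CACHE["ids"] = np.array(m.long_ids + m.short_ids)
    return _ID_CACHE["ids"]


def draw_subject_spec(config: CohortConfig, group: str, thi: float,
                      rng: np.random.Generator) -> SubjectSpec:
    """Draw one subject's generating parameters given group and THI."""
    tin = group == "tinnitus"
    if tin:
        loudness = float(np.clip(round(thi / 8.0 + rng.normal(0, 1.5)), 1, 10))
        annoyance = float(np.clip(round(thi / 8.0 + rng.normal(0, 1.5)), 1, 10))
        duration = float(np.clip(rng.normal(11.5, 8.8), 0.5, 25.0))
        age = float(np.clip(rng.normal(48.4, 12.9), 25, 68))
    else:
        loudness = annoyance = 0.0
        duration = 0.0
        age = float(np.clip(rng.normal(45.5, 16.7), 25, 76))

    conn = default_connectivity(config.connectivity_base)
    if tin:
        conn[("right", "frontal", "HbO")] = _clip_rho(
            config.connectivity_base
            + config.d_frontal_hbo_right
            + config.duration_slope_frontal_hbo * (duration - 11.5)
        )
        conn[("left", "frontal", "HbO")] = _clip_rho(
            config.connectivity_base
            + config.d_frontal_hbo_left
            + config.duration_slope_frontal_hbo * (duration - 11.5)
        )
        conn[("right", "occipital", "HbR")] = _clip_rho(
            config.connectivity_base
            + config.d_occipital_hbr_right
            + config.loudness_slope_occ_hbr * (loudness - 5.0)
        )
        if config.d_severity_conn and thi > 36:
            for roi in ("frontal", "occipital"):
                conn[("right", roi, "HbR")] = _clip_rho(
                    conn[("right", roi, "HbR")] + config.d_severity_conn
                )

    peak = config.evoked_hbo_peak_control - (config.evoked_reduction_tinnitus if tin else 0.0)
    all_ids = _default_channel_ids()
    bad = frozenset(
        int(cid) for cid in all_ids[rng.random(len(all_ids)) < config.bad_channel_rate]
    )
    spec = SubjectSpec(
        group=group,
        thi=thi,
        loudness=loudness,
        annoyance=annoyance,
        duration_years=duration,
        age=age,
        hearing_4k=float(np.clip(rng.normal(25, 12), 0, 70)),
        hearing_8k=float(np.clip(rng.normal(30, 14), 0, 70)),
        evoked_amp=default_evoked_amp(peak),
        connectivity=conn,
        bad_channels=bad,
    )
    return replace(spec, **config.spec_overrides)


def _draw_thi(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """THI scores for the tinnitus group with fixed severity-band counts."""
    n_low, n_high = config.severity_counts
    n_extra = config.n_tinnitus - n_low - n_high
    if n_extra < 0:
        raise ValueError("severity counts exceed tinnitus group size")
    thi = np.concatenate(
        [
            np.round(rng.uniform(4, 36, size=n_low)),
            np.round(rng.uniform(37, 60, size=n_high)),
            np.round(rng.uniform(4, 60, size=n_extra)),
        ]
    )
    rng.shuffle(thi)
    return thi


def simulate_cohort(
    config: CohortConfig, rng: np.random.Generator
) -> Iterator[SimulatedSubject]:
    """Generate a cohort one subject at a time (streaming, memory-light)."""
    montage = build_montage()
    thi_values = _draw_thi(config, rng)
    plan = [("control", 0.0)] * config.n_control + [
        ("tinnitus", float(v)) for v in thi_values
    ]
    for k, (group, thi) in enumerate(plan):
        schedule = build_schedule(config.schedule, rng)
        spec = draw_subject_spec(config, group, thi, rng)
        recording, truth = simulate_subject(spec, montage, schedule, rng)
        yield SimulatedSubject(
            subject_id=f"S{k + 1:03d}", spec=spec, recording=recording, truth=truth
        )
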