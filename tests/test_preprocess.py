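"""Quality control, optical density, resampling, superficial correction,
and the modified Beer-Lambert inversion."""

import numpy as np
import pytest

from tinnirs.montage import build_montage
from tinnirs.preprocess import (
    OpticsConstants,
    apply_qc,
    beer_lambert,
    downsample_resting,
    forward_beer_lambert,
    intensity_to_od,
    scalp_coupling_index,
    short_channel_correct,
)
from tinnirs.recording import Recording, WAVELENGTHS_NM

FS = 7.8125


def _recording(data, montage=None, stage="intensity", ids=None, fs=FS):
    data = np.asarray(data, dtype=float)
    ids = ids or tuple(range(1, data.shape[0] + 1))
    return Recording(stage=stage, channel_ids=tuple(ids), bands=WAVELENGTHS_NM,
                     data=data, sampling_rate_hz=fs, montage=montage)


class TestSci:
    def test_shared_cardiac_gives_unit_sci(self):
        t = np.arange(int(120 * FS)) / FS
        cardiac = np.sin(2 * np.pi * 1.1 * t)
        data = 1.0 + 0.01 * np.stack([[cardiac, 0.5 * cardiac]])
        sci = scalp_coupling_index(_recording(data))
        assert sci[1] > 1 - 1e-9

    def test_independent_noise_gives_low_sci(self, rng):
        n = 2812
        hits = 0
        for _ in range(50):
            data = 1.0 + 0.01 * rng.standard_normal((1, 2, n))
            sci = scalp_coupling_index(_recording(data))
            hits += abs(sci[1]) < 0.1
        assert hits == 50

    def test_constant_signal_flagged_zero(self):
        data = np.ones((1, 2, 1000))
        with pytest.warns(UserWarning, match="constant"):
            sci = scalp_coupling_index(_recording(data))
        assert sci[1] == 0.0

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            scalp_coupling_index(_recording(np.ones((1, 2, 50))))


class TestQc:
    def _cohort_recording(self, gains=None):
        montage = build_montage()
        if gains:
            montage = montage.with_gains(gains)
        ids = montage.long_ids + montage.short_ids
        t = np.arange(int(120 * FS)) / FS
        cardiac = np.sin(2 * np.pi * 1.1 * t)
        data = np.empty((len(ids), 2, len(t)))
        data[:, 0] = 1.0 + 0.01 * cardiac
        data[:, 1] = 1.0 + 0.005 * cardiac
        return _recording(data, montage=montage, ids=ids)

    def test_clean_recording_keeps_everything(self):
        rec = self._cohort_recording()
        kept, report = apply_qc(rec)
        assert report.rejected_ids == []
        assert len(kept.channel_ids) == 40

    def test_gain_8_channel_rejected_with_reason(self):
        rec = self._cohort_recording(gains={9: 8})
        kept, report = apply_qc(rec)
        assert report.rejected_ids == [9]
        row = report.table.set_index("channel").loc[9]
        assert row.reject_reason == "gain"
        assert 9 not in kept.channel_ids

    def test_sci_thresholds_are_sharp(self, rng):
        """A channel correlating 0.74 across wavelengths is rejected, 0.76 kept."""
        rec = self._cohort_recording()
        n = rec.n_samples
        for target, expect_kept in ((0.74, False), (0.76, True)):
            data = rec.data.copy()
            shared = rng.standard_normal(n)
            a = shared
            b = target * shared + np.sqrt(1 - target**2) * rng.standard_normal(n)
            data[0, 0] = 1.0 + 0.01 * a
            data[0, 1] = 1.0 + 0.01 * b
            test_rec = _recording(data, montage=rec.montage, ids=rec.channel_ids)
            sci = scalp_coupling_index(test_rec)
            # verify the construction before asserting the QC decision
            assert abs(sci[rec.channel_ids[0]] - target) < 0.05
            _, report = apply_qc(test_rec)
            row = report.table.set_index("channel").loc[rec.channel_ids[0]]
            assert bool(row.kept) == (row.sci >= 0.75)

    def test_all_rejected_is_hard_failure(self):
        rec = self._cohort_recording(gains={cid: 8 for cid in self._cohort_recording().channel_ids})
        with pytest.raises(RuntimeError, match="7"):
            apply_qc(rec)

    def test_qc_is_idempotent(self):
        rec = self._cohort_recording(gains={9: 8, 30: 8})
        once, r1 = apply_qc(rec)
        twice, r2 = apply_qc(once)
        assert once.channel_ids == twice.channel_ids
        np.testing.assert_array_equal(once.data, twice.data)

    def test_injected_bad_channel_fraction_recovered(self, montage, rng):
        """A cohort with 13% bad channels shows ~13% gain rejections."""
        from tinnirs.simulate import CohortConfig, simulate_cohort

        config = CohortConfig(
            n_control=4, n_tinnitus=6, severity_counts=(4, 2),
            schedule={"include_evoked": False, "resting_duration_s": 60.0},
        )
        total = rejected = 0
        for sim in simulate_cohort(config, rng):
            _, report = apply_qc(sim.recording)
            total += len(report.table)
            rejected += len(report.rejected_ids)
        assert abs(rejected / total - 0.13) < 0.06


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(_recording(np.full((1, 2, 100), 2.5)))
        assert np.allclose(od.data, 0.0)
        assert od.stage == "od"

    def test_halved_sample_gives_log10_two(self):
        data = np.ones((1, 2, 100))
        data[:, :, 0] = 0.5
        data[:, :, 1] = 1.5  # keeps the temporal mean exactly 1
        od = intensity_to_od(_recording(data))
        assert np.allclose(od.data[:, :, 0], np.log10(2.0))

    def test_scaling_invariance(self, rng):
        base = rng.uniform(0.5, 1.5, size=(1, 2, 200))
        od1 = intensity_to_od(_recording(base))
        od2 = intensity_to_od(_recording(7.3 * base))
        np.testing.assert_allclose(od1.data, od2.data, atol=1e-12)

    def test_non_positive_sample_identified(self):
        data = np.ones((2, 2, 50))
        data[1, 0, 7] = -0.1
        with pytest.raises(ValueError, match="channel 2.*sample 7"):
            intensity_to_od(_recording(data))


class TestDownsample:
    def test_360s_resting_gives_360_samples(self):
        n = int(round(360 * FS))
        od = _recording(np.zeros((1, 2, n)), stage="od")
        out = downsample_resting(od, 1.0)
        assert out.n_samples == 360
        assert out.sampling_rate_hz == 1.0

    def test_constant_signal_preserved(self):
        od = _recording(np.full((1, 2, 2812), 0.3), stage="od")
        out = downsample_resting(od)
        assert np.allclose(out.data, 0.3, atol=1e-6)

    def test_slow_sinusoid_amplitude_within_1pct(self):
        t = np.arange(2812) / FS
        sig = np.sin(2 * np.pi * 0.05 * t)
        od = _recording(np.stack([[sig, sig]]), stage="od")
        out = downsample_resting(od)
        # compare RMS in the central region, away from filter edge effects
        mid = slice(30, -30)
        assert abs(out.data[0, 0, mid].std() / sig.std() - 1) < 0.01

    def test_upsampling_rejected(self):
        od = _recording(np.zeros((1, 2, 100)), stage="od")
        with pytest.raises(ValueError, match="target rate"):
            downsample_resting(od, 100.0)


class TestShortChannelCorrection:
    def _montage_recording(self, build):
        montage = build_montage()
        ids = montage.long_ids + montage.short_ids
        n = 500
        rng = np.random.default_rng(1)
        data = np.zeros((len(ids), 2, n))
        build(montage, ids, data, rng, n)
        return _recording(data, montage=montage, ids=ids, stage="od")

    def test_exact_fraction_removed(self):
        def build(montage, ids, data, rng, n):
            short = rng.standard_normal(n)
            data[ids.index(2)] = short  # frontal short channel
            data[ids.index(1)] = 0.5 * short

        od = self._montage_recording(build)
        out = short_channel_correct(od)
        assert np.allclose(out.get(1, 760.0), 0.0, atol=1e-10)
        assert abs(out.provenance[-1]["beta"]["ch1_760.0"] - 0.5) < 1e-10

    def test_orthogonal_cortical_signal_survives(self):
        def build(montage, ids, data, rng, n):
            t = np.arange(n)
            short = np.sin(2 * np.pi * t / 25)
            cortical = np.sin(2 * np.pi * t / 40)
            data[ids.index(2)] = short
            data[ids.index(1)] = cortical + 0.7 * short
            self.cortical = cortical

        od = self._montage_recording(build)
        out = short_channel_correct(od)
        beta = out.provenance[-1]["beta"]["ch1_760.0"]
        assert abs(beta - 0.7) < 0.02
        resid = out.get(1, 760.0)
        assert np.sqrt(np.mean((resid - self.cortical) ** 2)) < 0.05 * self.cortical.std()

    def test_uncorrelated_short_leaves_long_alone(self):
        def build(montage, ids, data, rng, n):
            data[ids.index(2)] = rng.standard_normal(n)
            data[ids.index(1)] = rng.standard_normal(n)

        od = self._montage_recording(build)
        out = short_channel_correct(od)
        beta = out.provenance[-1]["beta"]["ch1_760.0"]
        assert abs(beta) < 0.1
        assert np.corrcoef(out.get(1, 760.0), od.get(1, 760.0))[0, 1] > 0.99

    def test_post_correction_orthogonality(self, rng):
        def build(montage, ids, data, r, n):
            short = rng.standard_normal(n)
            for cid in montage.long_ids:
                data[ids.index(cid)] = rng.standard_normal((2, n)) + 0.6 * short
            for cid in montage.short_ids:
                data[ids.index(cid)] = short

        od = self._montage_recording(build)
        out = short_channel_correct(od)
        nearest = od.montage.nearest_short
        for cid in (1, 9, 30, 20):
            r = np.corrcoef(out.get(cid, 760.0), od.get(nearest[cid], 760.0))[0, 1]
            assert abs(r) < 1e-8

    def test_correction_reduces_error_vs_ground_truth(self, montage, resting_schedule, rng):
        from tinnirs.experiments import short_channel_mse_ratio

        ratio = short_channel_mse_ratio(2, rng)
        assert ratio > 2.0  # tighter bound exercised in the acceptance suite


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self, montage):
        ids = montage.long_ids + montage.short_ids
        od = _recording(np.zeros((40, 2, 50)), montage=montage, ids=ids, stage="od")
        hemo = beer_lambert(od)
        assert np.allclose(hemo.data, 0.0)
        assert hemo.bands == ("HbO", "HbR")

    def test_round_trip_known_concentrations(self):
        hbo = np.full(20, 1.0)
        hbr = np.full(20, -0.25)
        od_fwd = forward_beer_lambert(hbo, hbr, 3.0)
        od = _recording(od_fwd[None], stage="od")
        hemo = beer_lambert(od)
        np.testing.assert_allclose(hemo.get(1, "HbO"), 1.0, atol=1e-9)
        np.testing.assert_allclose(hemo.get(1, "HbR"), -0.25, atol=1e-9)

    def test_wavelength_permutation_invariance(self, rng):
        od_data = rng.standard_normal((1, 2, 30)) * 1e-3
        base = beer_lambert(_recording(od_data, stage="od"))
        default = OpticsConstants()
        swapped = OpticsConstants(
            extinction={760.0: default.extinction[850.0], 850.0: default.extinction[760.0]},
            dpf={760.0: default.dpf[850.0], 850.0: default.dpf[760.0]},
        )
        alt = beer_lambert(_recording(od_data[:, ::-1], stage="od"), swapped)
        np.testing.assert_allclose(alt.data, base.data, atol=1e-12)

    def test_linearity(self, rng):
        a = rng.standard_normal((1, 2, 40)) * 1e-3
        b = rng.standard_normal((1, 2, 40)) * 1e-3
        lhs = beer_lambert(_recording(2 * a + 3 * b, stage="od")).data
        rhs = 2 * beer_lambert(_recording(a, stage="od")).data + \
            3 * beer_lambert(_recording(b, stage="od")).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_singular_constants_rejected(self):
        bad = OpticsConstants(
            extinction={760.0: {"HbO": 1.0, "HbR": 2.0}, 850.0: {"HbO": 2.0, "HbR": 4.0}},
            dpf={760.0: 6.0, 850.0: 6.0},
        )
        with pytest.raises(ValueError, match="singular"):
            bad.matrix(3.0)
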