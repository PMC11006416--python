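"""Recording preprocessing: artifact blanking, filtering, averaging, QC."""

import numpy as np
import pytest
from scipy import signal as sig

from apemu.errors import ValidationError
from apemu.preprocess import (ARTIFACT_BLANK_MS, FILTER_CUTOFF_KHZ,
                              FILTER_FS_KHZ, RawRecording, average_and_resample,
                              blank_stimulus, filter_beat, final_grid,
                              preprocess_recording, qc_exclude_pair,
                              synthesize_recording)
from apemu.simulator import APTrace, ConductanceSet, PacingProtocol


@pytest.fixture(scope="module")
def clean_ap():
    from apemu.simulator import simulate_ap

    return simulate_ap(ConductanceSet(), PacingProtocol(n_beats=40))


class TestBlankStimulus:
    @staticmethod
    def _beat_with_artifact(rmp=-85.0):
        t = np.arange(0.0, 1000.1, 0.1)
        vm = np.full_like(t, rmp)
        vm[(t >= 0.3) & (t <= 0.8)] += 40.0  # artifact spike
        vm[(t > 2.0) & (t < 300.0)] = 20.0
        return APTrace(times=t, vm=vm)

    def test_artifact_replaced_by_end_rmp(self):
        out = blank_stimulus(self._beat_with_artifact())
        m = out.times <= ARTIFACT_BLANK_MS
        assert np.all(out.vm[m] == out.vm[-1])

    def test_idempotent_when_already_flat(self):
        b = self._beat_with_artifact()
        once = blank_stimulus(b)
        twice = blank_stimulus(once)
        assert np.array_equal(once.vm, twice.vm)

    def test_never_touches_later_samples(self):
        b = self._beat_with_artifact()
        out = blank_stimulus(b)
        m = b.times > ARTIFACT_BLANK_MS
        assert np.array_equal(out.vm[m], b.vm[m])


class TestFilterBeat:
    def test_dc_gain_is_one(self):
        t = np.arange(0.0, 1000.1, 0.1)
        out = filter_beat(APTrace(times=t, vm=np.full_like(t, -80.0)))
        assert np.allclose(out.vm, -80.0, atol=1e-9)

    @pytest.mark.parametrize("f_khz,rtol", [(10.0, 0.05), (0.1, 0.01)])
    def test_sinusoid_attenuation_matches_analytic_response(self, f_khz, rtol):
        """Measured gain equals |H|^2 of the designed Butterworth (zero-phase)."""
        t = np.arange(0.0, 200.0, 1.0 / FILTER_FS_KHZ)
        vm = np.sin(2 * np.pi * f_khz * t)
        out = filter_beat(APTrace(times=t, vm=vm))
        # analytic two-pass magnitude response at f
        b, a = sig.butter(2, FILTER_CUTOFF_KHZ / (FILTER_FS_KHZ / 2))
        _w, h = sig.freqz(b, a, worN=[2 * np.pi * f_khz / FILTER_FS_KHZ])
        expected = np.abs(h[0]) ** 2
        mid = (out.times > 50) & (out.times < 150)  # avoid edge transients
        measured = out.vm[mid].max()
        assert measured == pytest.approx(expected, rel=rtol)

    def test_too_short_beat_rejected(self):
        t = np.arange(0.0, 0.05, 0.01)
        with pytest.raises(ValidationError):
            filter_beat(APTrace(times=t, vm=np.zeros_like(t)))


class TestAverageAndResample:
    def test_identical_beats_average_to_any_beat(self, clean_ap):
        t = np.arange(0.0, 1000.1, 0.1)
        vm = np.interp(t, clean_ap.times, clean_ap.vm)
        rec = RawRecording(times=t, beats=np.tile(vm, (10, 1)))
        avg, qc = average_and_resample(rec)
        assert qc["max_sd_pre_peak"] < 1e-9 and qc["max_sd_post_peak"] < 1e-9
        assert np.allclose(avg.vm, np.interp(avg.times, t, vm), atol=1e-12)

    def test_final_grid_rates(self):
        g = final_grid()
        assert np.allclose(np.diff(g[g < 15.0 - 1e-9]), 0.01)
        assert np.allclose(np.diff(g[g >= 15.0]), 1.0)

    def test_averaging_reduces_noise_like_sqrt_n(self, clean_ap, rng):
        t = np.arange(0.0, 1000.1, 0.1)
        vm = np.interp(t, clean_ap.times, clean_ap.vm)
        noise_sd = 1.0
        beats = vm + noise_sd * rng.standard_normal((10, t.size))
        avg, _qc = average_and_resample(RawRecording(times=t, beats=beats))
        resid = avg.vm - np.interp(avg.times, t, vm)
        post = avg.times > 20.0
        assert np.std(resid[post]) < 2.5 * noise_sd / np.sqrt(10)

    def test_qc_flags_fire_on_jitter(self, clean_ap, rng):
        """Pre-peak SD above 7 mV (alignment mismatch) raises the QC flag."""
        rec = synthesize_recording(ConductanceSet(), noise_sd=0.1, jitter_sd=1.5,
                                   protocol=PacingProtocol(n_beats=40), seed=2)
        _avg, qc = preprocess_recording(rec)
        assert qc["flag_pre_peak"]


class TestEndToEnd:
    def test_zero_noise_recording_matches_simulator(self, clean_ap):
        rec = synthesize_recording(ConductanceSet(), noise_sd=0.0, jitter_sd=0.0,
                                   protocol=PacingProtocol(n_beats=40), seed=0)
        assert np.allclose(rec.beats[0], rec.beats[9])
        # outside the artifact window the beat equals the (delayed) simulated AP
        m = rec.times > 2.0
        expected = np.interp(rec.times[m] - 2.0, clean_ap.times, clean_ap.vm)
        assert np.allclose(rec.beats[0][m], expected, atol=1e-9)

    def test_pipeline_recovers_clean_ap_within_1mv(self, clean_ap):
        """1 mV beat noise: blank+filter+average recovers the AP to < 1 mV RMSE."""
        rec = synthesize_recording(ConductanceSet(), noise_sd=1.0, jitter_sd=0.05,
                                   protocol=PacingProtocol(n_beats=40), seed=7)
        avg, _qc = preprocess_recording(rec)
        m = avg.times > 5.0
        truth = np.interp(avg.times[m] - 2.0, clean_ap.times, clean_ap.vm)
        rmse = float(np.sqrt(np.mean((avg.vm[m] - truth) ** 2)))
        assert rmse < 1.0

    def test_fixed_seed_determinism(self):
        a = synthesize_recording(ConductanceSet(), seed=5,
                                 protocol=PacingProtocol(n_beats=30))
        b = synthesize_recording(ConductanceSet(), seed=5,
                                 protocol=PacingProtocol(n_beats=30))
        assert np.array_equal(a.beats, b.beats)

    def test_pipeline_idempotence(self, clean_ap):
        """Re-processing a processed trace changes it < 0.1 mV off the upstroke.

        Each low-pass pass re-smooths the near-discontinuous depolarization
        edge, so exact idempotence cannot hold in a few-ms window around the
        maximum slope; there the deviation stays bounded by a few mV.
        """
        rec = synthesize_recording(ConductanceSet(), noise_sd=0.5, jitter_sd=0.0,
                                   protocol=PacingProtocol(n_beats=40), seed=1)
        once, _ = preprocess_recording(rec)
        t = once.times
        again, _ = preprocess_recording(RawRecording(times=t, beats=once.vm[None, :]))
        common = again.times[again.times <= t[-1]]
        a = np.interp(common, once.times, once.vm)
        b = np.interp(common, again.times, again.vm)
        t_up = common[np.argmax(np.gradient(a, common))]
        off_edge = np.abs(common - t_up) > 5.0
        assert np.max(np.abs(a - b)[off_edge]) < 0.1
        assert np.max(np.abs(a - b)) < 5.0

    def test_csv_round_trip(self, tmp_path):
        rec = synthesize_recording(ConductanceSet(), seed=3, fs_khz=2.0,
                                   protocol=PacingProtocol(n_beats=30))
        p = tmp_path / "rec.csv"
        rec.to_csv(p)
        back = RawRecording.from_csv(p)
        assert np.allclose(back.beats, rec.beats)


class TestQCExcludePair:
    def test_exclusion_rules(self):
        from apemu.biomarkers import BiomarkerRanges, BiomarkerSet

        ranges = BiomarkerRanges()
        ok = BiomarkerSet(RMP=-87, dVmMax=300, Peak=40, APD40=200, APD50=250,
                          APD90=320, Tri90_40=120)
        long_apd = BiomarkerSet(RMP=-87, dVmMax=300, Peak=40, APD40=200,
                                APD50=250, APD90=500, Tri90_40=300)
        assert not qc_exclude_pair(ok, ok, ranges)
        assert qc_exclude_pair(ok, long_apd, ranges)
        assert qc_exclude_pair(long_apd, ok, ranges)  # symmetric
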