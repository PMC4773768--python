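"""CAP recording I/O, peak detection, latency/NCV and block index."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from demyelin.cap_signals import (
    CapRecording,
    analyze,
    block_index,
    detect_peaks,
    latency,
    ncv_from_latency,
    read_recording,
    write_recording,
)
from demyelin.exceptions import (
    DegenerateLatencyError,
    FormatError,
    NoPeakError,
)
from demyelin.synthetic_data import CapSpec, gen_cap_recording


@pytest.fixture
def clean_recording():
    return gen_cap_recording(CapSpec(latency_ms=0.93, noise_sd_mv=0.0))


class TestRecordingIO:
    def test_round_trip(self, clean_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(clean_recording, path)
        back = read_recording(path)
        np.testing.assert_allclose(back.proximal_mv,
                                   clean_recording.proximal_mv, atol=1e-8)
        assert back.sampling_rate_khz == \
            clean_recording.sampling_rate_khz
        assert back.electrode_distance_cm == 3.0

    def test_missing_column(self, clean_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(clean_recording, path)
        df = pd.read_csv(path).drop(columns=["distal_mV"])
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="distal_mV"):
            read_recording(path)

    def test_missing_sidecar_key(self, clean_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(clean_recording, path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        del meta["sampling_rate_khz"]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(FormatError, match="sampling_rate_khz"):
            read_recording(path)

    def test_missing_sidecar_file(self, clean_recording, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording(clean_recording, path)
        path.with_suffix(".json").unlink()
        with pytest.raises(FormatError, match="sidecar"):
            read_recording(path)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.01, 0.025, 0.03])
        with pytest.raises(FormatError, match="uniform"):
            CapRecording(time_ms=t, proximal_mv=np.zeros(4),
                         distal_mv=np.zeros(4), sampling_rate_khz=100.0)


class TestDetectPeaks:
    def test_recovers_programmed_peaks_noiseless(self):
        rec = gen_cap_recording(
            CapSpec(latency_ms=0.93, t0_ms=1.0, noise_sd_mv=0.0))
        t_p, t_d, a_p, a_d = detect_peaks(rec)
        assert t_p == pytest.approx(1.00, abs=0.01)
        assert t_d == pytest.approx(1.93, abs=0.01)
        assert a_p == pytest.approx(1.0, rel=0.01)
        assert a_d == pytest.approx(0.9, rel=0.01)

    def test_flat_channel_raises(self):
        n = 500
        t = np.arange(n) / 100.0
        sig = np.exp(-0.5 * ((t - 2.0) / 0.2) ** 2)
        rec = CapRecording(time_ms=t, proximal_mv=sig,
                           distal_mv=np.zeros(n),
                           sampling_rate_khz=100.0)
        with pytest.raises(NoPeakError, match="distal"):
            detect_peaks(rec)

    def test_identical_channels_degenerate_downstream(self):
        spec = CapSpec(latency_ms=0.9, noise_sd_mv=0.0)
        rec = gen_cap_recording(spec)
        twin = CapRecording(time_ms=rec.time_ms,
                            proximal_mv=rec.proximal_mv,
                            distal_mv=rec.proximal_mv,
                            sampling_rate_khz=rec.sampling_rate_khz)
        t_p, t_d, _, _ = detect_peaks(twin)
        assert t_p == t_d
        with pytest.raises(DegenerateLatencyError):
            analyze(twin)

    def test_blank_window_masks_early_artifact(self):
        rec = gen_cap_recording(CapSpec(latency_ms=0.9, noise_sd_mv=0.0))
        spiked = CapRecording(
            time_ms=rec.time_ms,
            proximal_mv=rec.proximal_mv
            + 5.0 * (rec.time_ms < 0.05),     # stimulus artifact
            distal_mv=rec.distal_mv,
            sampling_rate_khz=rec.sampling_rate_khz)
        t_p, _, a_p, _ = detect_peaks(spiked, artifact_blank_ms=0.3)
        assert t_p == pytest.approx(1.0, abs=0.01)
        assert a_p == pytest.approx(1.0, rel=0.02)


class TestLatencyAndNcv:
    @pytest.mark.parametrize("tp,td,expected", [
        (1.0, 2.0, 1.0), (0.5, 2.6, 2.1)])
    def test_latency(self, tp, td, expected):
        assert latency(tp, td) == pytest.approx(expected)

    def test_non_causal_ordering(self):
        with pytest.raises(DegenerateLatencyError):
            latency(2.0, 1.0)

    @pytest.mark.parametrize("lat,dist,expected", [
        (1.0, 3.0, 30.0), (2.1, 3.0, 14.2857)])
    def test_ncv_from_latency(self, lat, dist, expected):
        assert ncv_from_latency(lat, dist) == pytest.approx(expected,
                                                            rel=1e-4)

    def test_zero_latency_error(self):
        with pytest.raises(DegenerateLatencyError):
            ncv_from_latency(0.0, 3.0)

    @given(lat=st.floats(0.1, 10.0), dist=st.floats(0.5, 10.0))
    def test_homogeneity(self, lat, dist):
        v = ncv_from_latency(lat, dist)
        assert ncv_from_latency(lat, 2 * dist) == pytest.approx(2 * v)
        assert ncv_from_latency(2 * lat, dist) == pytest.approx(v / 2)


class TestBlockIndex:
    def test_no_block_at_baseline_ratio(self):
        assert block_index(1.0, 0.9, baseline_ratio=0.9).value == \
            pytest.approx(0.0)

    def test_complete_block(self):
        res = block_index(1.0, 0.0, baseline_ratio=0.9)
        assert res.value == 1.0
        assert not res.clamped

    def test_linearity_half_ratio(self):
        assert block_index(1.0, 0.45, baseline_ratio=0.9).value == \
            pytest.approx(0.5)

    @given(gain=st.floats(0.1, 50.0))
    def test_common_gain_invariance(self, gain):
        a, b = 1.2, 0.7
        base = block_index(a, b, 0.9).value
        assert block_index(gain * a, gain * b, 0.9).value == \
            pytest.approx(base, rel=1e-9)

    def test_clamp_flag(self):
        res = block_index(1.0, 2.0, baseline_ratio=1.0)
        assert res.value == 0.0
        assert res.clamped


class TestAnalyze:
    def test_time_shift_invariance(self):
        """Shifting both channels by the same offset keeps the latency."""
        a = gen_cap_recording(CapSpec(latency_ms=1.5, noise_sd_mv=0.0,
                                      t0_ms=1.0))
        b = gen_cap_recording(CapSpec(latency_ms=1.5, noise_sd_mv=0.0,
                                      t0_ms=2.2))
        assert analyze(a).latency_ms == \
            pytest.approx(analyze(b).latency_ms, abs=1e-6)

    def test_full_measurement(self):
        spec = CapSpec(latency_ms=1.5, noise_sd_mv=0.0)
        m = analyze(gen_cap_recording(spec), baseline_ratio=0.9)
        assert m.latency_ms == pytest.approx(1.5, abs=0.01)
        assert m.ncv_mps == pytest.approx(20.0, rel=0.01)
        assert m.block_index == pytest.approx(0.0, abs=0.01)

    def test_noisy_recovery_within_two_percent(self):
        """Mean measured NCV over seeds is within 2 % of programmed."""
        for lat in (0.9, 2.1):
            spec0 = CapSpec(latency_ms=lat, noise_sd_mv=0.1)
            ncvs = [analyze(gen_cap_recording(
                CapSpec(latency_ms=lat, noise_sd_mv=0.1,
                        seed=s))).ncv_mps for s in range(30)]
            prog = spec0.programmed_ncv_mps
            assert np.mean(ncvs) == pytest.approx(prog, rel=0.02)
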