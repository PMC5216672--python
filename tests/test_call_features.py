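import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chorusspace import calibration as cal
from chorusspace.call_features import (
    ANALYSIS_BAND,
    CallAnnotation,
    CallMeasurement,
    ExcludedFrog,
    aggregate_frog,
    annotations_from_table,
    call_duration,
    call_rate,
    centroid_frequency,
    downsample,
    measure_calls,
    read_selection_table,
    select_calls,
    source_level_1m,
    write_selection_table,
)
from chorusspace.commspace import PropagationParams, received_level
from chorusspace.synthetic_data import synthesize_scene
from conftest import tone_clip


def multi_tone(freqs_amps, duration=1.0, sample_rate=44100.0):
    t = np.arange(int(duration * sample_rate)) / sample_rate
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return cal.AudioClip(x, sample_rate, units="pa")


class TestCallAnnotation:
    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            CallAnnotation(begin=5.0, end=5.0)

    def test_bad_frequency_bounds_rejected(self):
        with pytest.raises(ValueError):
            CallAnnotation(begin=0.0, end=1.0, low_freq=3000.0, high_freq=1000.0)


class TestSelectionTableIO:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "Begin Time (s)": [1.0, 2.5],
                "End Time (s)": [1.3, 2.8],
                "Low Freq (Hz)": [1000.0, 1000.0],
                "High Freq (Hz)": [4500.0, 4500.0],
                "frog": ["F1", "F2"],
            }
        )
        path = tmp_path / "sel.txt"
        write_selection_table(df, path)
        back = read_selection_table(path)
        pd.testing.assert_frame_equal(back, df)
        anns = annotations_from_table(back)
        assert anns[0].begin == 1.0 and anns[1].frog == "F2"

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        pd.DataFrame({"Begin Time (s)": [1.0]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            read_selection_table(path)


class TestSelectCalls:
    def test_overlap_flag_filtered(self):
        anns = [
            CallAnnotation(0.0, 0.3),
            CallAnnotation(1.0, 1.3, overlapped=True),
            CallAnnotation(2.0, 2.3),
        ]
        kept = select_calls(anns, [70.0, 70.0, 70.0], ambient_db=50.0, min_snr=10.0)
        assert kept == [anns[0], anns[2]]

    def test_low_snr_rejected(self):
        anns = [CallAnnotation(0.0, 0.3)]
        assert select_calls(anns, [55.0], ambient_db=50.0, min_snr=10.0) == []

    def test_high_snr_all_kept(self):
        anns = [CallAnnotation(t, t + 0.3) for t in (0.0, 1.0, 2.0)]
        kept = select_calls(anns, [80.0, 81.0, 82.0], ambient_db=50.0, min_snr=10.0)
        assert kept == anns

    def test_empty_input(self):
        assert select_calls([], [], ambient_db=50.0) == []


class TestCallDuration:
    def test_buffer_rule(self):
        d, window = call_duration(CallAnnotation(10.00, 10.30), buffer_s=0.05)
        assert d == pytest.approx(0.30)
        assert window == (pytest.approx(9.95), pytest.approx(10.35))

    def test_zero_buffer(self):
        _, window = call_duration(CallAnnotation(1.0, 1.4), buffer_s=0.0)
        assert window == (1.0, 1.4)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            _, window = call_duration(
                CallAnnotation(0.01, 0.30), buffer_s=0.05, clip_duration=0.32
            )
        assert window == (0.0, 0.32)

    @given(st.floats(0.0, 0.5))
    def test_duration_invariant_to_buffer(self, buffer_s):
        d, _ = call_duration(CallAnnotation(2.0, 2.7), buffer_s=buffer_s)
        assert d == pytest.approx(0.7)


class TestCentroidFrequency:
    def test_pure_tone(self):
        clip = tone_clip(2000.0, 1.0, 1.0)
        bin_width = clip.sample_rate / 4096
        assert centroid_frequency(clip, (0.0, 1.0)) == pytest.approx(2000.0, abs=bin_width)

    def test_equal_power_tone_pair_symmetry(self):
        clip = multi_tone([(1500.0, 1.0), (2500.0, 1.0)])
        bin_width = clip.sample_rate / 4096
        assert centroid_frequency(clip, (0.0, 1.0)) == pytest.approx(2000.0, abs=bin_width)

    def test_out_of_band_tone_excluded(self):
        clip = multi_tone([(500.0, 1.0), (3000.0, 1.0)])
        bin_width = clip.sample_rate / 4096
        assert centroid_frequency(clip, (0.0, 1.0)) == pytest.approx(3000.0, abs=bin_width)

    def test_zero_in_band_energy_is_nan(self):
        clip = tone_clip(200.0, 0.5, 1.0)
        assert np.isnan(centroid_frequency(clip, (0.0, 0.5)))

    def test_short_segment_zero_padded(self):
        clip = tone_clip(2000.0, 0.05, 1.0)  # 2205 samples < 4096
        bin_width = clip.sample_rate / 4096
        # windowed short segment: allow a couple of bins of spectral leakage
        assert centroid_frequency(clip, (0.0, 0.05)) == pytest.approx(
            2000.0, abs=3 * bin_width
        )

    @given(st.floats(0.01, 100.0))
    def test_amplitude_invariance(self, scale):
        base = tone_clip(2300.0, 0.5, 1.0)
        scaled = cal.AudioClip(base.samples * scale, base.sample_rate, units="pa")
        c0 = centroid_frequency(base, (0.0, 0.5))
        c1 = centroid_frequency(scaled, (0.0, 0.5))
        assert c0 == pytest.approx(c1, rel=1e-9)


class TestSourceLevel1m:
    def test_two_metres_no_attenuation(self):
        p = PropagationParams(excess_attenuation=0.0)
        assert source_level_1m(60.0, 2.0, p) == pytest.approx(66.02, abs=0.005)

    def test_one_metre_with_attenuation(self):
        p = PropagationParams(excess_attenuation=0.2)
        assert source_level_1m(60.0, 1.0, p) == pytest.approx(60.2)

    def test_ten_metres_with_attenuation(self):
        p = PropagationParams(excess_attenuation=0.2)
        assert source_level_1m(60.0, 10.0, p) == pytest.approx(82.0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            source_level_1m(60.0, 0.0)

    @given(
        s=st.floats(50.0, 110.0),
        r=st.floats(0.5, 200.0),
        ae=st.floats(0.0, 1.0),
    )
    def test_inverts_forward_attenuation(self, s, r, ae):
        p = PropagationParams(excess_attenuation=ae)
        rl = received_level(s, r, p)
        assert source_level_1m(rl, r, p) == pytest.approx(s, abs=1e-9)


class TestCallRate:
    def test_basic(self):
        assert call_rate(45, 90.0) == pytest.approx(30.0)

    def test_zero_calls(self):
        assert call_rate(0, 60.0) == 0.0

    def test_fractional(self):
        assert call_rate(17, 210.0) == pytest.approx(4.857, abs=5e-4)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            call_rate(5, 0.0)


class TestAggregateFrog:
    def _m(self, duration, centroid=2400.0, spl_db=70.0, sl=90.0):
        return CallMeasurement(duration, centroid, spl_db, sl)

    def test_means(self):
        rec = aggregate_frog([self._m(0.2), self._m(0.4)], rate=10.0, frog="F1")
        assert rec.duration_s == pytest.approx(0.3)
        assert rec.n_calls == 2

    def test_single_call_identity(self):
        m = self._m(0.27, centroid=2550.0, sl=88.5)
        rec = aggregate_frog([m], rate=5.0, frog="F2", site="S1")
        assert rec.duration_s == m.duration
        assert rec.centroid_frequency_hz == m.centroid_frequency
        assert rec.source_level_db == m.source_level
        assert rec.call_rate_cpm == 5.0

    def test_empty_gives_exclusion_record(self):
        rec = aggregate_frog([], rate=0.0, frog="F3")
        assert isinstance(rec, ExcludedFrog)
        assert "no accepted calls" in rec.reason


class TestDownsample:
    def test_rate_and_length(self):
        clip = tone_clip(2000.0, 1.0, 1.0)
        out = downsample(clip, 11025)
        assert out.sample_rate == 11025.0
        assert out.n_samples == 11025

    def test_in_band_content_preserved(self):
        clip = tone_clip(2000.0, 1.0, 1.0)
        out = downsample(clip, 11025)
        assert cal.rms(out.samples) == pytest.approx(cal.rms(clip.samples), rel=0.01)


@pytest.fixture(scope="module")
def scene():
    frogs = pd.DataFrame(
        [
            {"frog": "F1", "distance_m": 5.0, "source_level_db": 90.0,
             "centroid_frequency_hz": 2400.0, "duration_s": 0.30, "call_rate_cpm": 12.0},
            {"frog": "F2", "distance_m": 6.0, "source_level_db": 87.0,
             "centroid_frequency_hz": 2600.0, "duration_s": 0.25, "call_rate_cpm": 6.0},
        ]
    )
    calib = cal.CalibrationSpec(mic_sensitivity=-36.0, gain=20.0)
    params = PropagationParams(excess_attenuation=0.2)
    res = synthesize_scene(frogs, 40.0, 30.0, params, calib, seed=13)
    return frogs, calib, params, res


class TestSceneRoundTrip:
    """Full pipeline on synthesized scenes recovers truth."""

    def test_snr_at_least_20(self, scene):
        frogs, _, params, _ = scene
        for row in frogs.itertuples(index=False):
            rl = received_level(row.source_level_db, row.distance_m, params)
            assert rl - 40.0 >= 20.0

    def test_recovery_per_frog(self, scene):
        frogs, calib, params, res = scene
        anns = annotations_from_table(res.truth)
        for row in frogs.itertuples(index=False):
            mine = [a for a in anns if a.frog == row.frog]
            accepted, meas = measure_calls(
                res.clip, mine, calib, row.distance_m, 40.0, params
            )
            # truth annotations: every call accepted -> exact call rate
            assert len(accepted) == len(mine)
            rate = call_rate(len(accepted), res.clip.duration)
            assert rate == pytest.approx(row.call_rate_cpm)
            rec = aggregate_frog(meas, rate, row.frog)
            assert rec.source_level_db == pytest.approx(row.source_level_db, abs=1.0)
            bin_width = 11025.0 / 4096  # downsampled analysis rate
            assert rec.centroid_frequency_hz == pytest.approx(
                row.centroid_frequency_hz, abs=2 * bin_width
            )
            assert rec.duration_s == pytest.approx(row.duration_s, abs=1e-6)
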