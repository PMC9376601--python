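import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tremorscore as ts
from tests.conftest import brute_force_top_median


def make_ratio(values, df=0.125):
    values = np.asarray(values, dtype=float)
    return ts.Spectrum(np.arange(values.size) * df, values, "ratio")


class TestSmoothSpectrum:
    def test_preserves_constants(self):
        sp = make_ratio(np.full(401, 3.0))
        out = ts.smooth_spectrum(sp, 1.0)
        np.testing.assert_allclose(out.values, 3.0, rtol=1e-12)

    def test_impulse_mass_conserved(self):
        """A unit impulse spreads into a discrete Gaussian of total mass 1."""
        values = np.zeros(401)
        values[200] = 1.0
        out = ts.smooth_spectrum(make_ratio(values), 1.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(out.values) == 200

    def test_linearity_two_impulses(self):
        a = np.zeros(401)
        a[100] = 1.0
        b = np.zeros(401)
        b[300] = 1.0
        sa = ts.smooth_spectrum(make_ratio(a), 1.0).values
        sb = ts.smooth_spectrum(make_ratio(b), 1.0).values
        sab = ts.smooth_spectrum(make_ratio(a + b), 1.0).values
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12)
        # far-apart impulses smooth into identical (shifted) kernels
        np.testing.assert_allclose(sa[100 - 30 : 100 + 30], sb[300 - 30 : 300 + 30])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ts.ParameterError):
            ts.smooth_spectrum(make_ratio(np.ones(401)), 0.0)


class TestWindowIndex:
    def test_flat_ratio_ties_break_to_lowest_frequency(self):
        wi = ts.window_index(make_ratio(np.ones(401)))
        assert wi.value == pytest.approx(1.0)
        assert wi.peak_freq == 3.5

    def test_smoothed_bump_peak_matches_convolution_oracle(self):
        """Gaussian bump (height 4, sd 1.5 Hz) on baseline 1, smoothed with
        sigma=1 Hz: two Gaussians convolve, so the peak is
        1 + 4 * 1.5/sqrt(1.5² + 1²)."""
        freqs = np.arange(401) * 0.125
        values = 1.0 + 4.0 * np.exp(-0.5 * ((freqs - 6.0) / 1.5) ** 2)
        wi = ts.window_index(make_ratio(values))
        expected = 1.0 + 4.0 * 1.5 / np.sqrt(1.5**2 + 1.0**2)
        assert wi.peak_freq == pytest.approx(6.0, abs=0.125)
        assert wi.value == pytest.approx(expected, rel=0.01)

    def test_out_of_band_bump_excluded(self):
        freqs = np.arange(401) * 0.125
        values = 1.0 + 10.0 * np.exp(-0.5 * ((freqs - 11.0) / 0.3) ** 2)
        wi = ts.window_index(make_ratio(values))
        assert wi.peak_freq <= 10.0  # only the in-band tail contributes

    def test_band_outside_grid_rejected(self):
        sp = make_ratio(np.ones(10))  # grid ends at 1.125 Hz
        with pytest.raises(ts.ParameterError):
            ts.window_index(sp)


def _indices(values, freqs=None):
    freqs = freqs if freqs is not None else [6.0] * len(values)
    return [
        ts.WindowIndex(value=v, peak_freq=f, window_start=0.0, channel="la_x")
        for v, f in zip(values, freqs)
    ]


class TestAggregateScore:
    def test_top_third_of_nine(self):
        score = ts.aggregate_score(_indices(range(1, 10)))
        assert score.n_windows_used == 3  # kept {9, 8, 7}
        assert score.index == 8.0

    def test_constant_values(self):
        for n in (1, 5, 84):
            assert ts.aggregate_score(_indices([2.5] * n)).index == 2.5

    def test_84_windows_midpoint_median(self):
        rng = np.random.default_rng(11)
        values = rng.random(84).tolist()
        score = ts.aggregate_score(_indices(values))
        assert score.n_windows_used == 28
        top = sorted(values, reverse=True)[:28]
        assert score.index == pytest.approx(0.5 * (top[13] + top[14]), abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ts.DataError):
            ts.aggregate_score([])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=200)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, values):
        score = ts.aggregate_score(_indices(values))
        assert score.n_windows_used == math.ceil(len(values) / 3)
        assert score.index == brute_force_top_median(values)

    def test_dominant_freq_is_median_of_kept(self):
        values = [1, 2, 3, 10, 11, 12]
        freqs = [4.0, 4.0, 4.0, 6.0, 7.0, 8.0]
        score = ts.aggregate_score(_indices(values, freqs))
        assert score.n_windows_used == 2  # values 12, 11 -> freqs 8, 7
        assert score.dominant_freq == 7.5


class TestToDecibel:
    def _score(self, index):
        return ts.TremorScore(
            index=index, n_windows_total=84, n_windows_used=28, dominant_freq=6.0
        )

    @pytest.mark.parametrize(
        "index, mean, expected_db",
        [(2.0, 2.0, 0.0), (20.0, 2.0, 10.0), (0.02, 2.0, -20.0)],
    )
    def test_forced_points(self, index, mean, expected_db):
        ref = ts.ControlReference(
            mean_index=mean, n_subjects=7, band=(3.5, 10.0), pipeline_config_hash=""
        )
        out = ts.to_decibel(self._score(index), ref)
        assert out.db == pytest.approx(expected_db, abs=1e-12)
        assert out.control_mean == mean

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ts.ParameterError):
            ts.to_decibel(self._score(1.0), 0.0)


class TestScoreRecording:
    def test_et_exceeds_control(self, et_recording, control_recording):
        et = ts.score_recording(et_recording)
        ctrl = ts.score_recording(control_recording)
        assert et.index > ctrl.index
        assert et.dominant_freq == pytest.approx(6.0, abs=0.25)

    def test_deterministic(self, short_et_recording):
        a = ts.score_recording(short_et_recording)
        b = ts.score_recording(short_et_recording)
        assert a == b

    def test_gain_invariance(self, short_et_recording):
        base = ts.score_recording(short_et_recording)
        for g in (0.1, 10.0):
            scaled = replace(
                short_et_recording,
                channels={k: g * v for k, v in short_et_recording.channels.items()},
            )
            out = ts.score_recording(scaled)
            assert out.index == pytest.approx(base.index, rel=1e-9)
            assert out.dominant_freq == base.dominant_freq

    def test_db_set_only_with_control(self, short_et_recording):
        plain = ts.score_recording(short_et_recording)
        assert plain.db is None
        ref = ts.ControlReference(
            mean_index=plain.index,
            n_subjects=1,
            band=(3.5, 10.0),
            pipeline_config_hash="",
        )
        scored = ts.score_recording(short_et_recording, control=ref)
        assert scored.db == pytest.approx(0.0, abs=1e-12)
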