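"""Filter frequency response, epoch segmentation, feature normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from entrofatigue import FilterSpec, Recording, apply_filters, epoch_recording, \
    normalize_features
from entrofatigue.preprocess import minmax_apply, minmax_fit, stack_epochsets

FS = 1000.0


def sine_recording(freq, fs=FS, seconds=4.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return Recording(subject_id=0, state="normal", channels=("Cz",),
                     data=amp * np.sin(2 * np.pi * freq * t)[None, :], fs=fs)


def rms(x):
    return float(np.sqrt(np.mean(x ** 2)))


class TestFilters:
    def test_mains_tone_attenuated_at_least_20_db(self):
        rec = sine_recording(50.0)
        out = apply_filters(rec)
        # compare on the interior to avoid filtfilt edge transients
        sl = slice(500, -500)
        assert rms(out.data[0][sl]) <= 0.1 * rms(rec.data[0][sl])

    def test_10_hz_passband_ripple_below_1_db(self):
        rec = sine_recording(10.0)
        out = apply_filters(rec)
        sl = slice(500, -500)
        assert abs(rms(out.data[0][sl]) / rms(rec.data[0][sl]) - 1.0) < 0.11

    def test_dc_offset_removed(self):
        rec = Recording(subject_id=0, state="normal", channels=("Cz",),
                        data=np.full((1, 8000), 100.0), fs=FS)
        out = apply_filters(rec)
        assert abs(out.data.mean()) < 1.0

    def test_shape_preserved(self):
        rec = sine_recording(10.0, seconds=2.0)
        assert apply_filters(rec).data.shape == rec.data.shape

    def test_band_edges_validated_against_nyquist(self):
        rec = sine_recording(10.0, fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filters(rec, FilterSpec(bp_high=45.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100.0))
    def test_filtering_is_linear_in_amplitude(self, scale):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(1, 2000))
        rec = Recording(subject_id=0, state="normal", channels=("Cz",),
                        data=data, fs=FS)
        scaled = Recording(subject_id=0, state="normal", channels=("Cz",),
                           data=scale * data, fs=FS)
        a = apply_filters(rec).data * scale
        b = apply_filters(scaled).data
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9 * scale)


class TestEpoching:
    def make(self, n_samples, fs=FS):
        return Recording(subject_id=0, state="fatigue", channels=("Cz", "Pz"),
                         data=np.arange(2 * n_samples, dtype=float).reshape(2, -1),
                         fs=fs)

    def test_exact_multiple_yields_all_epochs(self):
        sets = epoch_recording(self.make(5000), epoch_len_s=1.0)
        assert sets["Cz"].epochs.shape == (5, 1000)
        assert list(sets) == ["Cz", "Pz"]
        assert (sets["Pz"].labels == 1).all()

    def test_trailing_remainder_discarded(self):
        sets = epoch_recording(self.make(2500), epoch_len_s=1.0)
        assert sets["Cz"].epochs.shape == (2, 1000)
        # contiguous, in temporal order, half-open [k*L, (k+1)*L)
        np.testing.assert_array_equal(sets["Cz"].epochs[0], np.arange(1000.0))
        np.testing.assert_array_equal(sets["Cz"].epochs[1],
                                      np.arange(1000.0, 2000.0))

    def test_shorter_than_one_epoch_is_an_error(self):
        with pytest.raises(ValueError, match="shorter than one"):
            epoch_recording(self.make(999), epoch_len_s=1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n_samples=st.integers(100, 3000), epoch_len=st.sampled_from([0.1, 0.25, 1.0]))
    def test_sample_conservation(self, n_samples, epoch_len):
        rec = self.make(n_samples, fs=100.0)
        epoch_samples = int(round(epoch_len * 100.0))
        if n_samples < epoch_samples:
            return
        sets = epoch_recording(rec, epoch_len_s=epoch_len)
        n_epochs = sets["Cz"].epochs.shape[0]
        discarded = n_samples - n_epochs * epoch_samples
        assert 0 <= discarded < epoch_samples

    def test_stack_epochsets_concatenates_states(self):
        a = epoch_recording(self.make(2000))["Cz"]
        b = epoch_recording(self.make(3000))["Cz"]
        merged = stack_epochsets(a, b)
        assert merged.n_epochs == 5
        assert len(merged.labels) == 5


def tidy(values, subject=0, channel="Cz", feature="SE"):
    return pd.DataFrame({"subject": subject, "channel": channel,
                         "epoch": range(len(values)), "label": 0,
                         "feature": feature, "value": values})


class TestNormalize:
    def test_affine_minmax_maps_to_unit_interval(self):
        out = normalize_features(tidy([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out["value"], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_features(tidy([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(out["value"], 0.0)
        assert "constant" in caplog.text

    def test_saturated_range_unchanged(self):
        out = normalize_features(tidy([-1.0, 0.25, 1.0]))
        np.testing.assert_allclose(out["value"], [-1.0, 0.25, 1.0])

    def test_scaling_is_per_subject_and_per_feature(self):
        df = pd.concat([tidy([0.0, 1.0], subject=0), tidy([10.0, 30.0], subject=1)],
                       ignore_index=True)
        out = normalize_features(df)
        np.testing.assert_allclose(out["value"], [-1.0, 1.0, -1.0, 1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40, unique=True))
    def test_bounds_and_order_preserved(self, values):
        out = normalize_features(tidy(values))["value"].to_numpy()
        assert out.min() >= -1.0 - 1e-12 and out.max() <= 1.0 + 1e-12
        # the map is monotone: sorting by the input sorts the output
        assert (np.diff(out[np.argsort(values)]) >= -1e-12).all()

    def test_strict_mode_clips_test_values(self):
        bounds = minmax_fit(np.array([0.0, 10.0]))
        np.testing.assert_allclose(minmax_apply(np.array([-5.0, 5.0, 15.0]), bounds),
                                   [-1.0, 0.0, 1.0])
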