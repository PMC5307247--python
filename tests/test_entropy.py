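"""Entropy estimators: oracle equivalence, invariances, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from entrofatigue import DegenerateSignalError, EntropyParams, approximate_entropy, \
    extract_features, fuzzy_entropy, sample_entropy, spectral_entropy
from entrofatigue.preprocess import EpochSet
from entrofatigue.reference import naive_approximate_entropy, naive_fuzzy_entropy, \
    naive_sample_entropy


def random_series(kind, n, seed):
    rng = np.random.default_rng(seed)
    return {
        "gaussian": lambda: rng.normal(size=n),
        "uniform": lambda: rng.uniform(-1, 1, size=n),
        "ramp_noise": lambda: np.linspace(0, 1, n) + 0.1 * rng.normal(size=n),
        "ar1": lambda: np.array([x := 0.0] +  # noqa: F841
                                [x := 0.9 * x + rng.normal() for _ in range(n - 1)]),
    }[kind]()


class TestOracleEquivalence:
    """The vectorized implementations equal literal double-loop transcriptions."""

    @pytest.mark.parametrize("kind", ["gaussian", "uniform", "ramp_noise", "ar1"])
    @pytest.mark.parametrize("n", [100, 200])
    def test_all_three_template_entropies(self, kind, n):
        x = random_series(kind, n, seed=hash((kind, n)) % 2**31)
        p = EntropyParams()
        assert abs(sample_entropy(x, p) - naive_sample_entropy(x)) < 1e-12
        assert abs(approximate_entropy(x, p) - naive_approximate_entropy(x)) < 1e-12
        assert abs(fuzzy_entropy(x, p) - naive_fuzzy_entropy(x)) < 1e-12

    def test_linear_ramp_matches_oracle(self):
        x = np.arange(1.0, 51.0)
        assert abs(approximate_entropy(x) - naive_approximate_entropy(x)) < 1e-12


class TestDegenerateInputs:
    def test_constant_series_rejected(self):
        x = np.full(100, 5.0)
        for func in (sample_entropy, approximate_entropy, fuzzy_entropy):
            with pytest.raises(DegenerateSignalError):
                func(x)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.array([1.0, 2.0, 3.0]))

    def test_all_zero_signal_has_no_spectrum(self):
        with pytest.raises(DegenerateSignalError):
            spectral_entropy(np.zeros(1000), fs=1000.0)

    def test_narrow_band_with_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            spectral_entropy(np.random.default_rng(0).normal(size=1000), fs=1000.0,
                             p=EntropyParams(pe_band=(10.0, 11.0)))


class TestKnownValues:
    def test_alternating_series_has_zero_sample_entropy(self):
        x = np.tile([1.0, 2.0], 50)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_fuzzy_entropy_finite_where_sampen_diverges(self):
        """Near-constant series: SampEn hits the no-match sentinel, FuzzyEn
        stays finite and near zero (strictly positive membership)."""
        rng = np.random.default_rng(4)
        x = 5.0 + 1e-9 * np.cumsum(np.abs(rng.normal(size=60)) + 1.0)
        fe = fuzzy_entropy(x)
        assert np.isfinite(fe)

    def test_sinusoid_spectral_entropy_low(self):
        t = np.arange(1000) / 1000.0
        assert spectral_entropy(np.sin(2 * np.pi * 10 * t), fs=1000.0) <= 0.2

    def test_white_noise_spectral_entropy_high(self):
        x = np.random.default_rng(8).normal(size=1000)
        assert spectral_entropy(x, fs=1000.0) >= 0.9

    def test_two_equal_tones_give_ln2_unnormalized(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t)
        h = spectral_entropy(x, fs=1000.0, p=EntropyParams(pe_normalize=False))
        assert h == pytest.approx(np.log(2), rel=0.05)


class TestInvariances:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 100.0), b=st.floats(-50.0, 50.0))
    def test_affine_invariance_of_template_entropies(self, a, b):
        """r tracks the SD, so x -> a*x + b leaves AE/SE/FE unchanged."""
        x = np.random.default_rng(11).normal(size=150)
        y = a * x + b
        assert abs(sample_entropy(x) - sample_entropy(y)) < 1e-10
        assert abs(approximate_entropy(x) - approximate_entropy(y)) < 1e-10
        assert abs(fuzzy_entropy(x) - fuzzy_entropy(y)) < 1e-10

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_normalized_spectral_entropy_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500) + np.sin(2 * np.pi * 12 * np.arange(500) / 500.0
                                          * rng.uniform(0.5, 3.0))
        pe = spectral_entropy(x, fs=500.0)
        assert 0.0 <= pe <= 1.0

    def test_regularity_ordering_at_matched_sd(self):
        """sinusoid < sinusoid+noise < noise for SE/AE/FE, matched SD."""
        t = np.arange(1000) / 1000.0
        rng = np.random.default_rng(21)
        sin = np.sin(2 * np.pi * 10 * t)
        noise = rng.normal(size=1000)
        mix = sin + 0.5 * noise
        series = [s / s.std() for s in (sin, mix, noise)]
        for func in (sample_entropy, approximate_entropy, fuzzy_entropy):
            vals = [func(s) for s in series]
            assert vals[0] < vals[1] < vals[2], func.__name__


class TestExtractFeatures:
    def make_epochset(self, epochs, labels=None, fs=250.0):
        epochs = np.asarray(epochs)
        labels = np.zeros(len(epochs), int) if labels is None else labels
        return EpochSet(subject_id=0, channel="Cz", epochs=epochs,
                        labels=labels, fs=fs)

    def test_shape_and_alignment(self):
        rng = np.random.default_rng(0)
        es = self.make_epochset(rng.normal(size=(6, 250)),
                                labels=np.array([0, 0, 0, 1, 1, 1]))
        table = extract_features(es, ("SE", "FE", "AE", "PE"))
        assert len(table) == 24
        assert set(table.feature) == {"SE", "FE", "AE", "PE"}
        assert np.isfinite(table["value"]).all()
        labels = table[table.feature == "SE"].sort_values("epoch")["label"]
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1])

    def test_unknown_feature_rejected(self):
        es = self.make_epochset(np.random.default_rng(1).normal(size=(3, 250)))
        with pytest.raises(ValueError, match="unknown feature"):
            extract_features(es, ("SE", "XX"))

    def test_sampen_sentinels_imputed_with_column_max(self, caplog):
        """Very short regular epochs produce inf sample entropy; the policy
        replaces them with the column's finite maximum."""
        rng = np.random.default_rng(5)
        epochs = rng.normal(size=(20, 28))  # short enough that no-match epochs occur
        es = self.make_epochset(epochs)
        with caplog.at_level("WARNING"):
            table = extract_features(es, ("SE",))
        assert np.isfinite(table["value"]).all()
        assert "imputing" in caplog.text
        finite_vals = table["value"]
        # sentinels were replaced by the column maximum
        assert (finite_vals == finite_vals.max()).sum() >= 17

    def test_all_sentinel_column_aborts(self):
        rng = np.random.default_rng(5)
        es = self.make_epochset(rng.normal(size=(20, 24)))
        with pytest.raises(DegenerateSignalError, match="sentinel"):
            extract_features(es, ("SE",))

    def test_excess_degenerate_epochs_abort(self):
        epochs = np.vstack([np.full(250, 1.0),
                            np.random.default_rng(2).normal(size=(3, 250))])
        es = self.make_epochset(epochs)
        with pytest.raises(DegenerateSignalError, match="degenerate"):
            extract_features(es, ("SE",))
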