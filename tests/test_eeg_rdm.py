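"""Epoch preprocessing, channel selection and pairwise LDA decoding RDMs."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from schemarsa import (
    POSTERIOR_17,
    PairwiseDecoder,
    decode_series,
    pairwise_decode_rdm,
    preprocess_epochs,
    select_channels,
    simulate_eeg,
)
from schemarsa.eeg import _loto_lda_accuracies
from schemarsa.synthetic import EegDataset

from oracles import lda_loto_accuracy_oracle


def _dataset(epochs, labels, sfreq=200.0, names=None, t0=-200.0):
    n_times = epochs.shape[2]
    step = 1000.0 / sfreq
    times = t0 + step * np.arange(n_times)
    names = names or tuple(f"CH{i}" for i in range(epochs.shape[1]))
    return EegDataset(np.asarray(epochs, float), np.asarray(labels), times,
                      sfreq, tuple(names))


class TestPreprocess:
    def test_constant_trial_becomes_zero(self):
        ds = _dataset(np.full((2, 3, 80), 4.2), [0, 1])
        out = preprocess_epochs(ds, (-200.0, 0.0))
        assert np.allclose(out.epochs, 0.0)

    def test_downsampling_1000_to_200_hz_gives_5ms_step(self, rng):
        ds = _dataset(rng.normal(size=(2, 3, 1000)), [0, 1], sfreq=1000.0)
        out = preprocess_epochs(ds, (-200.0, 0.0), target_rate=200.0)
        assert out.sfreq == 200.0
        assert np.allclose(np.diff(out.times), 5.0)
        assert out.epochs.shape[2] == 200
        # boxcar decimation: each sample is the mean of 5 consecutive ones
        corrected = ds.epochs - ds.epochs[:, :, ds.times < 0].mean(2, keepdims=True)
        assert np.allclose(out.epochs[0, 0, 0], corrected[0, 0, :5].mean())

    def test_zero_mean_baseline_leaves_data_unchanged(self, rng):
        epochs = rng.normal(size=(2, 3, 80))
        pre = slice(0, 40)  # -200..0 ms at 200 Hz
        epochs[:, :, pre] -= epochs[:, :, pre].mean(axis=2, keepdims=True)
        ds = _dataset(epochs, [0, 1])
        out = preprocess_epochs(ds, (-200.0, 0.0))
        assert np.allclose(out.epochs, epochs)

    def test_non_integer_decimation_rejected(self, rng):
        ds = _dataset(rng.normal(size=(2, 3, 100)), [0, 1], sfreq=500.0)
        with pytest.raises(ValueError, match="integer multiple"):
            preprocess_epochs(ds, (-200.0, 0.0), target_rate=150.0)


class TestSelectChannels:
    def test_posterior_17_selection(self, rng):
        names = POSTERIOR_17 + ("Fz", "Cz")
        ds = _dataset(rng.normal(size=(4, 19, 10)), [0, 1, 0, 1], names=names)
        out = select_channels(ds, list(POSTERIOR_17))
        assert out.n_channels == 17
        assert out.channel_names == POSTERIOR_17
        assert np.array_equal(out.epochs, ds.epochs[:, :17])

    def test_order_follows_request_and_full_montage_is_identity(self, rng):
        ds = _dataset(rng.normal(size=(2, 3, 5)), [0, 1], names=("A", "B", "C"))
        out = select_channels(ds, ["C", "A"])
        assert out.channel_names == ("C", "A")
        assert np.array_equal(out.epochs[:, 0], ds.epochs[:, 2])
        same = select_channels(ds, ["A", "B", "C"])
        assert np.array_equal(same.epochs, ds.epochs)

    def test_unknown_and_empty_requests_rejected(self, rng):
        ds = _dataset(rng.normal(size=(2, 3, 5)), [0, 1], names=("A", "B", "C"))
        with pytest.raises(KeyError, match="X1"):
            select_channels(ds, ["A", "X1"])
        with pytest.raises(ValueError):
            select_channels(ds, [])


class TestPairwiseDecoding:
    def test_separable_clusters_decode_perfectly(self, rng):
        epochs = np.zeros((8, 2, 3))
        epochs[:4, 0] = 10.0
        epochs += 0.01 * rng.normal(size=epochs.shape)
        ds = _dataset(epochs, [0] * 4 + [1] * 4, t0=-5.0)
        rdm = pairwise_decode_rdm(ds, time_ms=5.0)
        assert rdm.values[0, 1] == 1.0

    def test_label_shuffled_data_is_at_chance(self, rng):
        epochs = rng.normal(size=(60, 5, 2))
        labels = np.repeat(np.arange(6), 10)
        ds = _dataset(epochs, labels, t0=-5.0)
        rdm = pairwise_decode_rdm(ds, time_ms=0.0)
        assert abs(np.nanmean(rdm.values) - 0.5) < 0.08
        assert np.nanmin(rdm.values) >= 0.0 and np.nanmax(rdm.values) <= 1.0

    @pytest.mark.parametrize("n_trials,n_chan", [(3, 2), (5, 4), (4, 3)])
    def test_matches_fold_enumeration_oracle(self, rng, n_trials, n_chan):
        """Vectorized downdate LDA equals one-fold-at-a-time enumeration."""
        X = rng.normal(size=(3, n_trials, n_chan))
        acc = _loto_lda_accuracies(X, shrinkage=0.05)
        for i in range(3):
            for j in range(i):
                want = lda_loto_accuracy_oracle(X[i], X[j], shrinkage=0.05)
                assert acc[i, j] == pytest.approx(want, abs=1e-12)
                assert acc[j, i] == acc[i, j]

    def test_agrees_with_sklearn_lda_when_unshrunk(self, rng):
        """Independent route: per-fold sklearn LDA with empirical covariance."""
        X = rng.normal(size=(2, 6, 3)) + np.array([0.0, 1.5])[:, None, None]
        acc = _loto_lda_accuracies(X, shrinkage=0.0)[1, 0]
        correct = []
        for k in range(6):
            train = np.vstack([np.delete(X[0], k, 0), np.delete(X[1], k, 0)])
            y = np.repeat([0, 1], 5)
            clf = LinearDiscriminantAnalysis(solver="lsqr").fit(train, y)
            correct.append(clf.predict(X[0, k][None])[0] == 0)
            correct.append(clf.predict(X[1, k][None])[0] == 1)
        assert acc == pytest.approx(np.mean(correct), abs=1e-12)

    def test_decoding_is_deterministic(self, rng):
        epochs = rng.normal(size=(12, 4, 6))
        ds = _dataset(epochs, [0, 1, 2] * 4, t0=-10.0)
        a = decode_series(ds).values
        b = decode_series(ds).values
        assert np.array_equal(a, b, equal_nan=True)

    def test_unequal_trial_counts_need_balance_flag(self, rng):
        epochs = rng.normal(size=(5, 3, 4))
        ds = _dataset(epochs, [0, 0, 0, 1, 1], t0=-10.0)
        with pytest.raises(ValueError, match="balance"):
            pairwise_decode_rdm(ds, time_ms=0.0)
        rdm = pairwise_decode_rdm(ds, time_ms=0.0, balance=True)
        assert np.isfinite(rdm.values[0, 1])


class TestDecodeSeries:
    def test_full_epoch_yields_201_rdms(self, small_set):
        study = simulate_eeg(small_set, n_subjects=1, n_channels=4, n_reps=2,
                             times=np.arange(-200.0, 801.0, 5.0), seed=3)
        series = decode_series(study.subjects[0])
        assert len(series) == 201
        assert series.values.shape == (201, 8, 8)
        assert series.times[0] == -200.0 and series.times[-1] == 800.0

    def test_estimator_params_roundtrip(self):
        dec = PairwiseDecoder(shrinkage=0.1, balance=True)
        assert dec.get_params() == {"shrinkage": 0.1, "balance": True}
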