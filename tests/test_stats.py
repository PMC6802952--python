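"""Group t-tests, Bonferroni, TFCE, sign permutation and latency bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from schemarsa import (
    PermutationScheme,
    bonferroni,
    group_ttest,
    latency_bootstrap,
    sign_permutation_correct,
    tfce_1d,
    tfce_batch,
)

from oracles import onesample_t_oracle, tfce_oracle


class TestGroupTtest:
    def test_closed_form_t(self):
        stat = group_ttest(np.array([[1.0], [2.0], [3.0]]))
        assert stat.t[0] == pytest.approx(2 * np.sqrt(3))
        assert stat.t[0] == pytest.approx(onesample_t_oracle([1.0, 2.0, 3.0]))

    def test_all_zero_betas(self):
        stat = group_ttest(np.zeros((5, 2)))
        assert np.array_equal(stat.t, [0.0, 0.0])
        assert np.array_equal(stat.p_uncorrected, [0.5, 0.5])

    def test_sign_flip_antisymmetry(self, rng):
        betas = rng.normal(size=(8, 4))
        a = group_ttest(betas)
        b = group_ttest(-betas)
        assert np.allclose(a.t, -b.t)
        assert np.allclose(a.p_uncorrected, 1.0 - b.p_uncorrected)

    def test_degenerate_variance_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero across-subject variance"):
            stat = group_ttest(np.full((4, 1), 2.0))
        assert np.isposinf(stat.t[0]) and stat.p_uncorrected[0] == 0.0


class TestBonferroni:
    def test_adjustment_and_cap(self):
        adjusted, sig = bonferroni(np.array([0.01, 0.5, 0.016]), m=3)
        assert np.allclose(adjusted, [0.03, 1.0, 0.048])
        assert list(sig) == [True, False, True]

    def test_m_below_test_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([0.1, 0.2]), m=1)


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert np.array_equal(tfce_1d(np.zeros(7)), np.zeros(7))
        assert np.array_equal(tfce_1d(-np.ones(7)), np.zeros(7))

    def test_raising_an_isolated_peak_increases_enhancement(self):
        base = np.array([0.0, 0.1, 2.0, 0.1, 0.0])
        taller = base.copy()
        taller[2] = 3.0
        assert tfce_1d(taller)[2] > tfce_1d(base)[2]

    def test_toy_map_matches_threshold_loop_oracle(self):
        m = np.array([0.2, 1.0, 0.8, -0.3, 0.5])
        assert np.allclose(tfce_1d(m), tfce_oracle(m), atol=1e-10)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        arrays(float, st.integers(1, 10),
               elements=st.floats(-3, 3, allow_nan=False, width=32))
    )
    def test_matches_oracle_on_arbitrary_short_maps(self, m):
        assert np.allclose(tfce_1d(np.asarray(m, float)), tfce_oracle(m), atol=1e-8)

    def test_batch_equals_per_map(self, rng):
        maps = rng.normal(size=(6, 12))
        batch = tfce_batch(maps)
        for k in range(6):
            assert np.allclose(batch[k], tfce_1d(maps[k]), atol=1e-10)

    def test_nonpositive_dh_rejected(self):
        with pytest.raises(ValueError, match="dh"):
            tfce_1d(np.ones(5), dh=0.0)


class TestSignPermutation:
    def test_identical_seed_gives_identical_mask(self, rng):
        betas = rng.normal(size=(8, 30)) + 0.3
        a = sign_permutation_correct(betas, PermutationScheme(300, seed=9))
        b = sign_permutation_correct(betas, PermutationScheme(300, seed=9))
        assert np.array_equal(a.sig_mask, b.sig_mask)
        assert np.array_equal(a.z, b.z)

    def test_strong_common_effect_window_is_flagged(self, rng):
        betas = 0.05 * rng.normal(size=(10, 40))
        betas[:, 15:25] += 2.0
        times = np.arange(0, 200, 5.0)
        stat = sign_permutation_correct(betas, PermutationScheme(500, seed=1),
                                        times=times)
        assert stat.sig_mask[15:25].all()
        assert not stat.sig_mask[:10].any()
        assert stat.onset_ms == times[15]
        assert 15 * 5 <= stat.peak_ms < 25 * 5
        assert stat.onset_ms <= stat.peak_ms

    def test_quantile_method_agrees_with_moment_on_clear_effect(self, rng):
        betas = 0.05 * rng.normal(size=(10, 30))
        betas[:, 10:20] += 2.0
        a = sign_permutation_correct(betas, PermutationScheme(500, seed=2))
        b = sign_permutation_correct(betas, PermutationScheme(500, seed=2),
                                     method="quantile")
        assert np.array_equal(a.sig_mask[10:20], b.sig_mask[10:20])

    def test_too_few_iterations_warn(self, rng):
        betas = rng.normal(size=(4, 10))
        with pytest.warns(RuntimeWarning, match="iterations"):
            sign_permutation_correct(betas, PermutationScheme(50, seed=0))


class TestLatencyBootstrap:
    @staticmethod
    def _sig_fn(betas):
        t = betas.mean(0) / (betas.std(0, ddof=1) / np.sqrt(betas.shape[0]))
        return t > 4.0

    def test_onset_recovered_at_high_snr(self, rng):
        times = np.arange(0, 300, 5.0)
        betas = 0.01 * rng.normal(size=(12, len(times)))
        betas[:, times >= 100] += 1.0
        out = latency_bootstrap(betas, sig_fn=self._sig_fn, n_boot=100, seed=3,
                                times=times)
        lo, hi = out["onset_ci"]
        assert lo <= 100 <= hi
        assert out["undefined_onset_rate"] == 0.0

    def test_null_betas_rarely_define_an_onset(self, rng):
        # bootstrap resampling fattens the t tails (duplicated subjects), so
        # the no-effect check uses a stricter threshold than the others
        betas = rng.normal(size=(12, 40))
        strict = lambda b: (b.mean(0) / (b.std(0, ddof=1) / np.sqrt(len(b)))) > 6.0
        out = latency_bootstrap(betas, sig_fn=strict, n_boot=60, seed=4)
        assert out["undefined_onset_rate"] > 0.8

    def test_noise_free_unimodal_peak_is_degenerate(self):
        times = np.arange(0, 100, 5.0)
        course = np.exp(-((times - 40.0) ** 2) / 200.0)
        # per-subject offsets keep across-subject SD constant over time, so
        # the group t is maximal exactly where the shared course peaks
        offsets = np.linspace(-0.05, 0.05, 6)[:, None]
        betas = np.tile(course, (6, 1)) + offsets
        out = latency_bootstrap(betas, sig_fn=self._sig_fn, n_boot=50, seed=5,
                                times=times)
        assert np.all(out["peaks"] == 40.0)
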