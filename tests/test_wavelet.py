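"""MHAT wavelet transform and optimal-scale selection."""

import warnings

import numpy as np
import pytest

from polsing import cwt, default_scales, mhat, scale_line, select_optimal_scale
from polsing.wavelet import select_scale_for_fields


def bump_train(n, scale, seed, spacing=40, amp=(3.0, 8.0), noise=0.2):
    """Non-overlapping MHAT bumps of a single injected scale plus noise."""
    rng = np.random.default_rng(seed)
    x = np.arange(n)
    q = np.zeros(n)
    centers = spacing * 0.6 + spacing * np.arange(n // spacing - 1)
    centers = centers + rng.uniform(-spacing / 5, spacing / 5, centers.size)
    for c in centers:
        q += rng.uniform(*amp) * mhat((x - c) / scale)
    return q + rng.normal(0, noise, n)


class TestMhat:
    @pytest.mark.parametrize("t,expected", [
        (0.0, 1.0),
        (1.0, 0.0),
        (-1.0, 0.0),
        (2.0, -3.0 * np.exp(-2.0)),
    ])
    def test_values(self, t, expected):
        assert mhat(t) == pytest.approx(expected, abs=1e-14)

    def test_discrete_zero_mean(self):
        t = np.arange(-40, 41) / 4.0  # wide grid, step 0.25
        assert abs(mhat(t).sum() * 0.25) < 1e-6


class TestCwt:
    def test_constant_profile_annihilated(self):
        field = cwt(np.ones(128), scales=np.arange(2, 17, 2))
        assert np.abs(field.Q).max() < 1e-6

    def test_unit_spike_closed_form(self):
        q = np.zeros(64)
        q[32] = 1.0
        field = cwt(q, scales=[4.0])
        b = np.arange(64)
        expected = 4.0**-0.5 * mhat((32 - b) / 4.0)
        np.testing.assert_allclose(field.Q[0], expected, atol=1e-8)

    def test_matched_filter_scale_recovery(self):
        x = np.arange(256)
        a0 = 12.0
        field = cwt(mhat((x - 128) / a0))
        best = field.scales[np.argmax(np.abs(field.Q[:, 128]))]
        assert abs(best - a0) <= 2.0  # one grid step

    def test_linearity(self, rng):
        q1, q2 = rng.normal(size=(2, 64))
        scales = [3.0, 8.0]
        lhs = cwt(2.5 * q1 - 1.5 * q2, scales).Q
        rhs = 2.5 * cwt(q1, scales).Q - 1.5 * cwt(q2, scales).Q
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_translation_covariance_integer_shift(self):
        x = np.arange(128)
        q = mhat((x - 50) / 6.0)
        k = 7
        qs = mhat((x - 50 - k) / 6.0)
        Q = cwt(q, scales=[4.0]).Q[0]
        Qs = cwt(qs, scales=[4.0]).Q[0]
        interior = slice(30, 90)
        np.testing.assert_allclose(Qs[interior.start + k: interior.stop + k],
                                   Q[interior], atol=1e-9)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            cwt(np.ones(4))  # too short
        with pytest.raises(ValueError):
            cwt(np.ones(64), scales=[])
        with pytest.raises(ValueError):
            cwt(np.ones(64), scales=[-1.0])

    def test_default_scale_grid(self):
        s = default_scales(256)
        assert s[0] == 2 and s[-1] == 64 and np.all(np.diff(s) == 2)


class TestScaleLine:
    def test_single_scale_field_returns_row(self, rng):
        field = cwt(rng.normal(size=32), scales=[5.0])
        np.testing.assert_array_equal(scale_line(field, 5.0), field.Q[0])

    def test_off_grid_nearest_with_warning(self, rng):
        field = cwt(rng.normal(size=32), scales=[4.0, 8.0])
        with pytest.warns(UserWarning, match="nearest"):
            line = scale_line(field, 5.0)
        np.testing.assert_array_equal(line, field.Q[0])

    def test_off_grid_exact_raises(self, rng):
        field = cwt(rng.normal(size=32), scales=[4.0, 8.0])
        with pytest.raises(ValueError):
            scale_line(field, 5.0, exact=True)


class TestSelectOptimalScale:
    def test_recovers_dispersion_peak_scale(self):
        """A* lands within one micro step of the full-grid dispersion argmax."""
        for seed in range(3):
            field = cwt(bump_train(256, 12.0, seed))
            oracle = field.scales[np.argmax(field.Q.var(axis=1))]
            sel = select_optimal_scale(field)
            assert not sel.fallback
            assert abs(sel.A_star - oracle) <= 2.0
            lo, hi = sel.macro_interval
            assert lo <= sel.A_star <= hi
            assert sel.A_star in field.scales

    def test_constant_profile_falls_back(self):
        field = cwt(np.full(256, 3.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_optimal_scale(field)
        assert sel.fallback

    def test_too_narrow_scale_span_raises(self, rng):
        field = cwt(rng.normal(size=64), scales=np.arange(2, 15, 2))
        with pytest.raises(ValueError, match="macro"):
            select_optimal_scale(field)

    def test_stable_across_seeds(self):
        stars = []
        for seed in range(5):
            sel = select_optimal_scale(cwt(bump_train(256, 12.0, 100 + seed)))
            stars.append(sel.A_star)
        med = np.median(stars)
        assert all(abs(a - med) <= 2.0 for a in stars)

    def test_pooled_selection_requires_common_grid(self, rng):
        f1 = cwt(rng.normal(size=256))
        f2 = cwt(rng.normal(size=128))
        with pytest.raises(ValueError):
            select_scale_for_fields([f1, f2])
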