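"""4C smoothing, quantile normalization and interaction calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from enhancerscope.fourc import (
    FourCProfile,
    call_interactions,
    conserved_calls,
    mask_viewpoint,
    profiles_from_counts,
    quantile_normalize,
    running_mean,
    InteractionCall,
)
from enhancerscope.intervals import FragmentMap, GenomicInterval
from enhancerscope.simulate import default_config, simulate_fourc_counts


class TestRunningMean:
    def test_constant_vector_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(running_mean(x, 21), 3.7)

    def test_impulse_spreads_over_window(self):
        x = np.zeros(200)
        x[100] = 1.0
        sm = running_mean(x, 21)
        support = np.flatnonzero(sm > 0)
        assert len(support) == 21
        assert np.allclose(sm[support], 1 / 21)
        assert support[0] == 90 and support[-1] == 110

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            running_mean(np.zeros(10), 4)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, size=60)
        mask = rng.random(60) < 0.2
        w = 7
        sm = running_mean(x, w, mask=mask)
        for i in range(60):
            if mask[i]:
                assert np.isnan(sm[i])
                continue
            lo, hi = max(0, i - 3), min(60, i + 4)
            vals = [x[j] for j in range(lo, hi) if not mask[j]]
            assert sm[i] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_circular_mode_preserves_mean(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, 101)
        sm = running_mean(x, 21, circular=True)
        assert sm.mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_masked_positions_stay_missing(self):
        x = np.arange(30.0)
        mask = np.zeros(30, dtype=bool)
        mask[10:13] = True
        sm = running_mean(x, 5, mask=mask)
        assert np.all(np.isnan(sm[10:13]))
        assert not np.any(np.isnan(np.delete(sm, slice(10, 13))))


class TestQuantileNormalize:
    def test_two_sample_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        out = quantile_normalize([a, b])
        assert np.allclose(out[0], [2.5, 3.5, 4.5])
        assert np.allclose(out[1], [2.5, 3.5, 4.5])

    def test_identical_samples_fixed_point(self):
        a = np.array([5.0, 1.0, 3.0, 2.0])
        out = quantile_normalize([a, a.copy()])
        assert np.allclose(out[0], a)
        assert np.allclose(out[1], a)

    def test_sorted_outputs_identical_across_samples(self):
        rng = np.random.default_rng(8)
        vs = [rng.uniform(0, 100, 500) for _ in range(4)]
        out = quantile_normalize(vs)
        ref = np.sort(out[0])
        for o in out[1:]:
            assert np.array_equal(np.sort(o), ref)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_preserves_within_sample_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        vs = [rng.integers(0, 20, 80).astype(float) for _ in range(3)]
        out = quantile_normalize(vs)
        for v, o in zip(vs, out):
            assert np.array_equal(rankdata(v), rankdata(o))

    def test_tied_values_get_average_target(self):
        a = np.array([1.0, 1.0, 5.0])
        b = np.array([2.0, 4.0, 6.0])
        out = quantile_normalize([a, b])
        # targets: (1+2)/2, (1+4)/2, (5+6)/2 = 1.5, 2.5, 5.5; the tie in
        # a spans the first two -> both get 2.0
        assert np.allclose(out[0], [2.0, 2.0, 5.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize([np.zeros(3), np.zeros(4)])

    def test_mask_excluded_and_stays_nan(self):
        a = np.array([1.0, 99.0, 3.0])
        b = np.array([2.0, 99.0, 4.0])
        mask = np.array([False, True, False])
        out = quantile_normalize([a, b], mask=mask)
        assert np.isnan(out[0][1]) and np.isnan(out[1][1])


def _uniform_fragmap(n=600, frag=250):
    boundaries = np.arange(n + 1) * frag
    return FragmentMap("chrT", boundaries, "GATC")


def _profile(values, viewpoint=300, fragmap=None):
    fm = fragmap or _uniform_fragmap(len(values))
    mask = mask_viewpoint(len(values), viewpoint)
    prof = FourCProfile(fm, viewpoint, np.asarray(values, float), mask=mask)
    prof.smoothed = running_mean(prof.raw, 21, mask=mask)
    return prof


class TestCallInteractions:
    def test_flat_profile_gives_no_calls(self):
        prof = _profile(np.full(600, 10.0))
        assert call_interactions(prof) == []

    def test_planted_peak_recovered(self):
        n = 600
        mids = (np.arange(n) + 0.5) * 250
        bg = 50.0 / (1.0 + np.abs(mids - 300 * 250) / 20_000)
        bg[400:412] *= 5.0
        prof = _profile(bg)
        calls = call_interactions(prof)
        planted = GenomicInterval("chrT", 400 * 250, 412 * 250)
        assert any(c.interval.overlaps(planted) for c in calls)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        n = 600
        mids = (np.arange(n) + 0.5) * 250
        y = rng.poisson(60.0 / (1.0 + np.abs(mids - 300 * 250) / 20_000)).astype(float)
        y[100:112] *= 6.0
        c1 = call_interactions(_profile(y))
        c2 = call_interactions(_profile(y * 37.5))
        assert [(c.interval.start, c.interval.end) for c in c1] == [
            (c.interval.start, c.interval.end) for c in c2
        ]

    def test_too_short_profile_rejected(self):
        prof = _profile(np.ones(9), viewpoint=5, fragmap=_uniform_fragmap(9))
        with pytest.raises(ValueError):
            call_interactions(prof, background_window=21)


class TestConservedCalls:
    def _call(self, s, e):
        return InteractionCall(GenomicInterval("c", s, e), 1.0)

    def test_identical_sets_returned(self):
        calls = [self._call(100, 200), self._call(500, 700)]
        out = conserved_calls([calls, calls])
        assert [(c.start, c.end) for c in out] == [(100, 200), (500, 700)]

    def test_disjoint_sets_empty(self):
        assert conserved_calls([[self._call(0, 10)], [self._call(20, 30)]]) == []

    def test_intersection_arithmetic(self):
        out = conserved_calls([[self._call(100, 200)], [self._call(150, 300)]])
        assert [(c.start, c.end) for c in out] == [(150, 200)]


class TestEndToEndProfiles:
    def test_planted_enhancer_contacts_called(self, locus, fragmap):
        cfg = default_config(seed=0)
        counts = simulate_fourc_counts(locus, cfg, fragmap, np.random.default_rng(21))
        profiles = profiles_from_counts(counts, fragmap, locus.viewpoint_pos)
        ike120 = locus.dhs_by_name(locus.ike120_name)
        target = GenomicInterval(locus.chrom, ike120.start - 2_000, ike120.end + 2_000)
        for prof in profiles:
            calls = call_interactions(prof)
            assert any(c.interval.overlaps(target) for c in calls)

    def test_identical_conditions_indistinguishable(self, locus, fragmap):
        # same parameters for both samples: after quantile normalization
        # the profiles' value distributions must agree (KS test)
        from scipy.stats import ks_2samp

        cfg = default_config(seed=0)
        counts = simulate_fourc_counts(locus, cfg, fragmap, np.random.default_rng(33))
        profiles = profiles_from_counts(counts, fragmap, locus.viewpoint_pos)
        a = profiles[0].normalized
        b = profiles[1].normalized
        ok = ~np.isnan(a) & ~np.isnan(b)
        assert ks_2samp(a[ok], b[ok]).pvalue > 0.01

    def test_background_only_smoothed_profile_decays(self, locus, fragmap):
        cfg = default_config(seed=0)
        cfg_nn = default_config(seed=0)
        cfg_nn.fourc.poisson_noise = False
        counts = simulate_fourc_counts(
            locus, cfg_nn, fragmap, 1, planted_peaks=False
        )
        profiles = profiles_from_counts(counts, fragmap, locus.viewpoint_pos)
        sm = profiles[0].smoothed
        vp = profiles[0].viewpoint
        right = sm[vp + 2 : vp + 500]
        ok = ~np.isnan(right)
        diffs = np.diff(right[ok])
        assert np.all(diffs <= 1e-9)  # monotone non-increasing rightwards
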