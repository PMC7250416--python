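"""Knight-Ruiz balancing, insulation scores, boundary calls, virtual 4C."""

import numpy as np
import pytest

from enhancerscope.hic import (
    ContactMatrix,
    InsulationProfile,
    KRConvergenceError,
    call_boundaries,
    delta_vector,
    insulation_scores,
    kr_balance,
    read_dense_matrix,
    read_triplet_matrix,
    virtual_4c,
    write_dense_matrix,
    write_triplet_matrix,
)
from enhancerscope.intervals import GenomicInterval
from enhancerscope.simulate import (
    HicParams,
    default_config,
    expected_hic_matrix,
    simulate_hic_matrix,
)


def _sinkhorn(A, iters=20_000, tol=1e-15):
    """Independent oracle: damped symmetric Sinkhorn iteration
    r <- sqrt(r / (A r)), whose fixed point satisfies r_i (A r)_i = 1."""
    r = np.ones(A.shape[0])
    for _ in range(iters):
        r_new = np.sqrt(r / (A @ r))
        if np.max(np.abs(r_new - r)) < tol * np.max(np.abs(r)):
            r = r_new
            break
        r = r_new
    return A * np.outer(r, r)


def _cm(counts, bin_size=10):
    return ContactMatrix("c", bin_size, np.asarray(counts, dtype=float))


class TestKRBalance:
    def test_two_by_two_closed_form(self):
        bal = kr_balance(_cm([[2.0, 1.0], [1.0, 2.0]]))
        assert np.allclose(bal.counts, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-9)
        assert np.allclose(bal.bias, 1 / np.sqrt(3), atol=1e-9)

    def test_doubly_stochastic_fixed_point(self):
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        bal = kr_balance(_cm(A))
        assert np.allclose(bal.counts, A, atol=1e-8)
        assert np.allclose(bal.bias, 1.0, atol=1e-6)

    def test_matches_sinkhorn_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            A = rng.uniform(0.5, 2.0, size=(20, 20))
            A = (A + A.T) / 2
            bal = kr_balance(_cm(A))
            rows = bal.counts.sum(axis=1)
            assert np.max(np.abs(rows - 1.0)) < 1e-8
            assert np.max(np.abs(bal.counts - _sinkhorn(A))) < 1e-6

    def test_invariant_under_symmetric_permutation(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0.5, 2.0, size=(15, 15))
        A = (A + A.T) / 2
        perm = rng.permutation(15)
        bal = kr_balance(_cm(A)).counts
        bal_p = kr_balance(_cm(A[np.ix_(perm, perm)])).counts
        assert np.allclose(bal[np.ix_(perm, perm)], bal_p, atol=1e-8)

    def test_zero_row_is_masked_and_propagates(self):
        A = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        bal = kr_balance(_cm(A))
        assert np.isnan(bal.bias[2])
        assert np.all(np.isnan(bal.counts[2]))
        assert np.allclose(bal.counts[:2, :2].sum(axis=1), 1.0, atol=1e-8)

    def test_nonconvergence_raises_with_diagnostics(self):
        A = np.ones((4, 4)) + np.diag(np.arange(4.0))
        with pytest.raises(KRConvergenceError) as exc:
            kr_balance(_cm(A), max_iter=0)
        assert exc.value.iterations == 0
        assert exc.value.residual > 0


class TestInsulation:
    def test_constant_matrix_gives_zero_scores(self):
        prof = insulation_scores(_cm(np.full((30, 30), 7.0)), window_bins=5)
        defined = prof.scores[~np.isnan(prof.scores)]
        assert np.allclose(defined, 0.0, atol=1e-12)
        assert np.isnan(prof.scores).sum() == 2 * 5

    def test_two_block_matrix_minimum_at_junction(self):
        n, b = 40, 20
        M = np.full((n, n), 1.0)
        M[:b, :b] = 10.0
        M[b:, b:] = 10.0
        prof = insulation_scores(_cm(M), window_bins=5)
        defined = np.flatnonzero(~np.isnan(prof.scores))
        i_min = defined[np.argmin(prof.scores[defined])]
        # the two window positions straddling the junction tie; the
        # plateau centre convention reports the downstream bin
        assert i_min in (b - 1, b)

    def test_distance_stationary_matrix_is_flat(self):
        n = 60
        idx = np.arange(n)
        M = 100.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
        prof = insulation_scores(_cm(M), window_bins=8)
        defined = prof.scores[~np.isnan(prof.scores)]
        assert np.ptp(defined) < 1e-9

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            insulation_scores(_cm(np.ones((10, 10))), window_bins=5)


class TestBoundaryCalls:
    def test_monotone_scores_give_no_boundaries(self):
        prof = InsulationProfile("c", 10, np.linspace(1, -1, 50))
        assert call_boundaries(prof).boundaries == []

    def test_strength_filter_flips_at_threshold(self):
        # V-shaped dips of depth a produce a delta range of 2a/3 with
        # flank 3; depths encode ranges 0.69 (uncalled) and 0.71 (called)
        scores = np.zeros(60)
        scores[20] = -3 * 0.69 / 2
        scores[40] = -3 * 0.71 / 2
        prof = InsulationProfile("c", 10, scores, strength_threshold=0.7)
        assert call_boundaries(prof).boundaries == [40]

    def test_delta_vector_hand_computed(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        d = delta_vector(scores, flank_bins=3)
        # delta(3) = mean(4,5,6) - mean(0,1,2) = 4
        assert d[3] == pytest.approx(4.0)
        assert d[4] == pytest.approx(4.0)
        assert np.isnan(d[2]) and np.isnan(d[5])  # flanks truncated

    def test_planted_boundary_recovered_from_simulation(self, locus):
        cfg = default_config(seed=42)
        counts = simulate_hic_matrix(locus, cfg, np.random.default_rng(42))
        bal = kr_balance(_cm(counts, bin_size=10_000))
        prof = call_boundaries(insulation_scores(bal))
        planted = locus.tad_boundary_bins(10_000)
        assert len(prof.boundaries) == len(planted)
        for called, true in zip(prof.boundaries, planted):
            assert abs(called - true) <= 1

    def test_translation_equivariance_noiseless(self, locus):
        cfg = default_config()
        cfg.hic.poisson_noise = False
        for shift_bp in (0, 50_000):
            model = locus
            boundaries = [b + shift_bp for b in (600_000, 1_250_000)]
            import dataclasses

            model = dataclasses.replace(
                locus,
                tad_boundaries_bp=boundaries,
                loop_anchors_bp=[],
            )
            expected = simulate_hic_matrix(model, cfg)
            bal = kr_balance(_cm(expected, bin_size=10_000))
            prof = call_boundaries(insulation_scores(bal))
            planted = [b // 10_000 for b in boundaries]
            # boundaries localize to within one bin of the junction (the
            # two straddling window positions tie up to balancing bias)
            assert len(prof.boundaries) == len(planted)
            assert all(
                abs(c - b) <= 1 for c, b in zip(prof.boundaries, planted)
            )


class TestVirtual4C:
    def test_row_extraction_with_anchor_masked(self):
        n = 5
        M = np.add.outer(np.arange(n), np.arange(n)).astype(float)
        track = virtual_4c(_cm(M), GenomicInterval("c", 30, 35))
        assert np.isnan(track.values[3])
        assert np.array_equal(np.delete(track.values, 3), [3, 4, 5, 7])

    def test_symmetry_between_anchors(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(1, 2, (12, 12))
        A = (A + A.T) / 2
        cm = _cm(A)
        t_a = virtual_4c(cm, GenomicInterval("c", 20, 25))
        t_b = virtual_4c(cm, GenomicInterval("c", 70, 75))
        assert t_a.values[7] == t_b.values[2]

    def test_anchor_spanning_two_bins_rejected(self):
        with pytest.raises(ValueError, match="point anchor"):
            virtual_4c(_cm(np.ones((5, 5))), GenomicInterval("c", 5, 15))

    def test_loop_bonus_detected_at_enhancer_bin(self, locus):
        cfg = default_config()
        cfg.hic.poisson_noise = False
        expected = simulate_hic_matrix(locus, cfg)
        bal = kr_balance(ContactMatrix(locus.chrom, 10_000, expected))
        prom_mid = locus.promoter.midpoint
        track = virtual_4c(
            bal, GenomicInterval(locus.chrom, prom_mid, prom_mid + 1)
        )
        prom_bin = prom_mid // 10_000
        enh_bin = locus.dhs_by_name(locus.ike120_name).midpoint // 10_000
        # strongest off-diagonal-trend contact: compare each bin against
        # others at the same distance from the anchor
        vals = track.values
        best = None
        for j in range(len(vals)):
            d = abs(j - prom_bin)
            if d < 3 or np.isnan(vals[j]):
                continue
            mirror = prom_bin + d if j < prom_bin else prom_bin - d
            if not (0 <= mirror < len(vals)) or np.isnan(vals[mirror]):
                continue
            ratio = vals[j] / vals[mirror]
            if best is None or ratio > best[1]:
                best = (j, ratio)
        assert best[0] == enh_bin


class TestMatrixIO:
    def test_dense_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        A = rng.poisson(5.0, (8, 8)).astype(float)
        A = A + A.T
        cm = ContactMatrix("chrS", 10_000, A)
        p = tmp_path / "m.tsv"
        write_dense_matrix(cm, p)
        back = read_dense_matrix(p)
        assert back.chrom == "chrS" and back.bin_size == 10_000
        assert np.allclose(back.counts, A)

    def test_triplet_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        A = rng.poisson(2.0, (10, 10)).astype(float)
        A = A + A.T
        cm = ContactMatrix("chrS", 5_000, A)
        p = tmp_path / "m.triplet"
        write_triplet_matrix(cm, p)
        back = read_triplet_matrix(p)
        assert np.allclose(back.counts, A)

    def test_simulated_matrix_symmetric_and_deterministic(self, locus):
        cfg = default_config(seed=5)
        m1 = simulate_hic_matrix(locus, cfg, 99)
        m2 = simulate_hic_matrix(locus, cfg, 99)
        assert np.array_equal(m1, m2)
        assert np.array_equal(m1, m1.T)

    def test_no_tads_no_noise_depends_only_on_distance(self, locus):
        import dataclasses

        model = dataclasses.replace(locus, tad_boundaries_bp=[], loop_anchors_bp=[])
        expected = expected_hic_matrix(model, HicParams())
        n = expected.shape[0]
        for k in (1, 5, 50):
            diag = np.diagonal(expected, offset=k)
            assert np.ptp(diag) == 0.0
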