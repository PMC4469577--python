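import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polybinmap.genotypes import A, B, H, MISSING
from polybinmap.linkage import (
    build_bins,
    build_genetic_map,
    estimate_rf_f2,
    group_bins,
    kosambi,
    order_bins,
    pairwise_rf_matrix,
    quality_matrix,
)


def _f2_vectors(r, n_ind, n_loci, rng):
    """Simulate linked codominant F2 loci spaced at recombination fraction r."""
    out = np.empty((n_loci, n_ind), dtype=np.int8)
    for j in range(n_ind):
        g1 = rng.integers(0, 2)
        g2 = rng.integers(0, 2)
        for i in range(n_loci):
            out[i, j] = g1 + g2
            if rng.random() < r:
                g1 ^= 1
            if rng.random() < r:
                g2 ^= 1
    return np.where(out == 0, A, np.where(out == 1, H, B)).astype(np.int8)


def _grid_loglik(g1, g2, r):
    """Independent likelihood oracle over the nine genotype-pair classes."""
    p = {
        (A, A): (1 - r) ** 2 / 4,
        (B, B): (1 - r) ** 2 / 4,
        (A, B): r**2 / 4,
        (B, A): r**2 / 4,
        (A, H): r * (1 - r) / 2,
        (H, A): r * (1 - r) / 2,
        (B, H): r * (1 - r) / 2,
        (H, B): r * (1 - r) / 2,
        (H, H): ((1 - r) ** 2 + r**2) / 2,
    }
    total = 0.0
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        total += math.log(max(p[(a, b)], 1e-300))
    return total


class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0) == 0.0

    def test_quarter(self):
        assert kosambi(0.25) == pytest.approx(25 * math.log(3), abs=1e-9)

    def test_small_r(self):
        assert kosambi(0.1) == pytest.approx(25 * math.log(1.2 / 0.8))
        assert kosambi(0.001) == pytest.approx(0.1, rel=1e-4)  # d ~ 100r

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)

    @given(st.floats(0, 0.499))
    def test_at_least_100r(self, r):
        assert kosambi(r) >= 100 * r - 1e-9

    @given(st.floats(0, 0.498), st.floats(1e-4, 1e-3))
    def test_strictly_increasing(self, r, dr):
        if r + dr < 0.5:
            assert kosambi(r + dr) > kosambi(r)

    def test_convex(self):
        rs = np.linspace(0, 0.49, 100)
        d = kosambi(rs)
        assert (np.diff(d, 2) > -1e-9).all()


class TestBins:
    def test_identical_vectors_one_bin(self):
        g = np.tile(np.array([A, H, B], dtype=np.int8), (2, 1))
        bins, assignment = build_bins(g)
        assert len(bins) == 1 and assignment.tolist() == [0, 0]
        assert bins[0].n_snps == 2

    def test_differing_vectors_two_bins(self):
        g = np.array([[A, H, B], [A, A, B]], dtype=np.int8)
        bins, assignment = build_bins(g)
        assert len(bins) == 2 and assignment.tolist() == [0, 1]

    def test_missing_sites_excluded(self):
        g = np.array([[A, H], [A, MISSING]], dtype=np.int8)
        bins, assignment = build_bins(g)
        assert len(bins) == 1 and assignment.tolist() == [0, -1]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_bins(np.empty((0, 0), dtype=np.int8))

    def test_bin_count_is_distinct_complete_columns(self, small_genotyped):
        _, geno = small_genotyped
        g = geno.unambiguous
        complete = ~(g == MISSING).any(axis=1)
        distinct = len({g[i].tobytes() for i in np.flatnonzero(complete)})
        bins, _ = build_bins(g)
        assert len(bins) == distinct

    def test_bin_count_matches_truth_patterns(self, small_cross, small_genotyped):
        # distinct complete truth columns = crossover-defined interval classes
        idx, geno = small_genotyped
        truth = small_cross.truth.genotypes[idx]
        n_truth_patterns = len({truth[i].tobytes() for i in range(truth.shape[0])})
        bins, _ = build_bins(geno.unambiguous)
        assert abs(len(bins) - n_truth_patterns) / n_truth_patterns < 0.25


class TestRecombinationEstimate:
    def test_identical_vectors(self):
        rng = np.random.default_rng(0)
        g = _f2_vectors(0.0, 59, 1, rng)[0]
        est = estimate_rf_f2(g, g)
        assert est.r < 1e-6
        assert est.lod > 6

    def test_independent_vectors_near_half(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(100):
            g1 = _f2_vectors(0.5, 59, 1, rng)[0]
            g2 = _f2_vectors(0.5, 59, 1, rng)[0]
            rs.append(estimate_rf_f2(g1, g2).r)
        assert abs(np.mean(rs) - 0.5) < 0.05

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(2)
        g = _f2_vectors(0.2, 40, 2, rng)
        assert estimate_rf_f2(g[0], g[1]).r == pytest.approx(
            estimate_rf_f2(g[1], g[0]).r, abs=1e-12
        )

    def test_low_confidence_flag(self):
        g = np.array([A] * 5, dtype=np.int8)
        assert estimate_rf_f2(g, g).low_confidence

    def test_em_maximizes_likelihood_vs_grid(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(1e-6, 0.5, 2001)
        for true_r in (0.05, 0.2, 0.35):
            g = _f2_vectors(true_r, 59, 2, rng)
            est = estimate_rf_f2(g[0], g[1])
            grid_best = grid[np.argmax([_grid_loglik(g[0], g[1], r) for r in grid])]
            assert est.r == pytest.approx(grid_best, abs=2e-3)

    def test_recovers_known_r(self):
        rng = np.random.default_rng(4)
        rs = [
            estimate_rf_f2(*_f2_vectors(0.1, 200, 2, rng)) .r for _ in range(50)
        ]
        assert abs(np.mean(rs) - 0.1) < 0.02

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(5)
        g = _f2_vectors(0.15, 59, 5, rng)
        r, lod = pairwise_rf_matrix(g)
        for i in range(5):
            for j in range(i + 1, 5):
                est = estimate_rf_f2(g[i], g[j])
                assert r[i, j] == pytest.approx(est.r, abs=1e-7)
                assert lod[i, j] == pytest.approx(est.lod, abs=1e-6)


class TestGrouping:
    def test_two_unlinked_chromosomes(self):
        rng = np.random.default_rng(6)
        g = np.vstack([_f2_vectors(0.02, 59, 5, rng), _f2_vectors(0.02, 59, 5, rng)])
        r, lod = pairwise_rf_matrix(g)
        groups = group_bins(r, lod)
        assert sorted(len(m) for m in groups) == [5, 5]

    def test_singleton_reported(self):
        rng = np.random.default_rng(7)
        g = np.vstack([_f2_vectors(0.02, 59, 4, rng), _f2_vectors(0.5, 59, 1, rng)])
        r, lod = pairwise_rf_matrix(g)
        groups = group_bins(r, lod)
        assert [4, 1] == [len(m) for m in groups]

    def test_simulated_grouping_matches_truth(self, small_cross, small_genotyped, small_mapped):
        idx, _ = small_genotyped
        m = small_mapped
        chrom = small_cross.snps.chrom[idx]
        big = [g for g in m.gmap.groups if len(g.bin_ids) > 2]
        assert len(big) == 2
        for group in big:
            chroms = {
                chrom[si]
                for bid in group.bin_ids
                for si in m.bins[bid].site_indices
            }
            assert len(chroms) == 1


class TestOrdering:
    def test_three_bin_chain(self):
        r = np.array(
            [[0.0, 0.05, 0.10], [0.05, 0.0, 0.05], [0.10, 0.05, 0.0]]
        )
        order, cum = order_bins([0, 1, 2], r)
        assert order in ([0, 1, 2], [2, 1, 0])
        assert cum[-1] == pytest.approx(2 * kosambi(0.05))

    def test_two_bins(self):
        r = np.array([[0.0, 0.2], [0.2, 0.0]])
        order, cum = order_bins([0, 1], r)
        assert cum[-1] == pytest.approx(kosambi(0.2))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        for k in (4, 6, 8):
            # distances from a noisy linear arrangement
            true_pos = np.sort(rng.uniform(0, 0.4, k))
            r = np.abs(true_pos[:, None] - true_pos[None, :])
            r = np.clip(r + rng.normal(0, 0.002, (k, k)), 0, 0.49)
            r = (r + r.T) / 2
            np.fill_diagonal(r, 0)
            order, _ = order_bins(list(range(k)), r)
            best_cost = min(
                sum(r[a, b] for a, b in zip(perm, perm[1:]))
                for perm in itertools.permutations(range(k))
            )
            cost = sum(r[a, b] for a, b in zip(order, order[1:]))
            assert cost == pytest.approx(best_cost, abs=1e-12)

    def test_reversal_leaves_length_invariant(self):
        rng = np.random.default_rng(9)
        g = _f2_vectors(0.05, 59, 8, rng)
        r, lod = pairwise_rf_matrix(g)
        order, cum = order_bins(list(range(8)), r)
        rev_total = sum(kosambi(min(r[a, b], 0.4999)) for a, b in zip(order[::-1], order[::-1][1:]))
        assert cum[-1] == pytest.approx(rev_total)

    def test_disconnected_group_rejected(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 0.0)
        with pytest.raises(ValueError, match="disconnected"):
            order_bins([0, 1, 2], r)


class TestMapRecovery:
    def test_simulated_map(self, small_cross, small_genotyped, small_mapped):
        from scipy.stats import spearmanr

        idx, _ = small_genotyped
        m = small_mapped
        chrom_pos = small_cross.snps.chrom_pos[idx]
        total_cm_true = sum(c.length_cm for c in small_cross.chromosomes)
        big = [g for g in m.gmap.groups if len(g.bin_ids) > 2]
        recovered = sum(g.length_cm for g in big)
        assert abs(recovered - total_cm_true) / total_cm_true < 0.15
        for group in big:
            true_bp = [
                np.median(chrom_pos[m.bins[b].site_indices]) for b in group.bin_ids
            ]
            rho = abs(spearmanr(np.arange(len(true_bp)), true_bp).statistic)
            assert rho >= 0.99


class TestQualityMatrix:
    def test_single_bin(self):
        q = quality_matrix(np.array([[A, H, B]], dtype=np.int8))
        assert q.shape == (1, 1) and q[0, 0] == 1.0

    def test_diagonal_concentration_and_shuffle_control(self):
        rng = np.random.default_rng(10)
        g = _f2_vectors(0.08, 59, 12, rng)
        r, _ = pairwise_rf_matrix(g)
        q = quality_matrix(g, r)
        k = q.shape[0]
        near = [q[i, j] for i in range(k) for j in range(k) if i != j and abs(i - j) <= 1]
        far = [q[i, j] for i in range(k) for j in range(k) if abs(i - j) > 3]
        assert np.mean(near) > np.mean(far)
        perm = rng.permutation(k)
        q_shuf = quality_matrix(g[perm], r[np.ix_(perm, perm)])
        near_s = [
            q_shuf[i, j] for i in range(k) for j in range(k) if i != j and abs(i - j) <= 1
        ]
        far_s = [q_shuf[i, j] for i in range(k) for j in range(k) if abs(i - j) > 3]
        assert np.mean(near) - np.mean(far) > np.mean(near_s) - np.mean(far_s)


class TestGroupLabels:
    def test_labels_applied(self):
        rng = np.random.default_rng(11)
        g = _f2_vectors(0.02, 59, 4, rng)
        r, lod = pairwise_rf_matrix(g)
        gmap = build_genetic_map(
            [b for b, _ in [build_bins(g)] for b in b],
            r,
            lod,
            group_labels={0: "A05"},
        )
        assert gmap.groups[0].name == "A05"
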