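import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polybinmap.genotypes import A, B, H, MISSING
from polybinmap.genotyping import (
    ErrorModel,
    build_blocks,
    call_initial_genotype,
    call_initial_matrix,
    evaluate_concordance,
    posterior_genotype,
    similarity_score,
    slide_windows,
    window_likelihoods,
)

DEFAULTS = ErrorModel()


def brute_force_posteriors(n1, n, error_model=DEFAULTS, priors=(0.25, 0.25, 0.5)):
    """Independent oracle: enumerate every read-assignment outcome.

    Each of the n reads independently carries the parent-1 allele with the
    per-genotype weight pair used by the closed-form likelihoods; the
    probability of observing exactly n1 parent-1 reads is the sum over all
    2^n sequences with that count.
    """
    e1, e2 = error_model.e1, error_model.e2
    weights = {
        A: (1 - e1, e2),
        B: (e1, 1 - e2),
        H: ((1 - e1 + e2) / 2, (1 + e1 - e2) / 2),
    }
    likes = {}
    for g, (w1, w2) in weights.items():
        total = 0.0
        for assignment in itertools.product((0, 1), repeat=n):
            if sum(assignment) != n1:
                continue
            p = 1.0
            for read in assignment:
                p *= w1 if read else w2
            total += p
        likes[g] = total
    unnorm = [likes[A] * priors[0], likes[B] * priors[1], likes[H] * priors[2]]
    z = sum(unnorm)
    return [u / z for u in unnorm]


class TestInitialCall:
    def test_depth_three_missing(self):
        assert call_initial_genotype(3, 0) == MISSING

    def test_only_parent1(self):
        assert call_initial_genotype(4, 0) == A

    def test_only_parent2(self):
        assert call_initial_genotype(0, 5) == B

    def test_both_alleles_het(self):
        assert call_initial_genotype(3, 1) == H

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        c1 = rng.integers(0, 8, size=(50, 7))
        c2 = rng.integers(0, 8, size=(50, 7))
        m = call_initial_matrix(c1, c2)
        for i in range(50):
            for j in range(7):
                assert m[i, j] == call_initial_genotype(int(c1[i, j]), int(c2[i, j]))


class TestSimilarityScore:
    def test_identity(self):
        v = np.array([A, H, B, A])
        assert similarity_score(v, v) == (1.0, 4)

    def test_mixed_example(self):
        s, n = similarity_score(np.array([A, H, B, A]), np.array([A, A, B, H]))
        assert s == pytest.approx((1 + 0.5 + 1 + 0.5) / 4)
        assert n == 4

    def test_full_mismatch_no_het(self):
        assert similarity_score(np.array([A, B]), np.array([B, A]))[0] == 0.0

    def test_missing_excluded(self):
        s, n = similarity_score(np.array([A, MISSING, B]), np.array([A, A, MISSING]))
        assert (s, n) == (1.0, 1)

    def test_all_missing_flagged(self):
        s, n = similarity_score(np.array([MISSING]), np.array([A]))
        assert n == 0 and math.isnan(s)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_score(np.array([A]), np.array([A, B]))

    @given(
        gz=st.lists(st.sampled_from([A, H, B, MISSING]), min_size=1, max_size=30),
        gj=st.lists(st.sampled_from([A, H, B, MISSING]), min_size=1, max_size=30),
    )
    def test_bounds_and_symmetry(self, gz, gj):
        k = min(len(gz), len(gj))
        a, b = np.array(gz[:k]), np.array(gj[:k])
        s, n = similarity_score(a, b)
        s2, n2 = similarity_score(b, a)
        assert n == n2
        if n:
            assert 0.0 <= s <= 1.0 and s == s2


class TestBlocks:
    def test_identical_sites_one_block(self):
        g = np.tile(np.array([A, H, B, A], dtype=np.int8), (10, 1))
        assert len(np.unique(build_blocks(g))) == 1

    def test_chimeric_flip_splits_at_boundary(self):
        rng = np.random.default_rng(1)
        v1 = rng.integers(0, 3, 30).astype(np.int8)
        v2 = (2 - v1).astype(np.int8)  # anticorrelated pattern
        g = np.vstack([np.tile(v1, (15, 1)), np.tile(v2, (15, 1))])
        blocks = build_blocks(g)
        assert blocks[14] != blocks[15]
        assert (blocks[:15] == blocks[0]).all() and (blocks[15:] == blocks[15]).all()

    def test_threshold_one_singletons_at_changes(self):
        g = np.array([[A, A], [A, H], [A, A]], dtype=np.int8)
        blocks = build_blocks(g, threshold=1.0)
        assert blocks.tolist() == [0, 1, 2]

    def test_empty(self):
        assert build_blocks(np.empty((0, 5), dtype=np.int8)).size == 0


class TestWindowLikelihoods:
    def test_error_free_limit(self):
        ll = window_likelihoods(8, 8, ErrorModel(0.0, 0.0))
        assert math.exp(ll[0]) == pytest.approx(1.0)
        assert ll[1] == -np.inf
        assert math.exp(ll[2]) == pytest.approx(2.0**-8)

    def test_all_parent1_reads_dominated_by_p1p1(self):
        ll = window_likelihoods(10, 10)
        assert math.exp(ll[0]) == pytest.approx(0.942**10, rel=1e-12)
        assert ll[0] > ll[2] > ll[1]

    def test_half_reads_favor_het(self):
        ll = window_likelihoods(5, 10)
        assert ll[2] > ll[0] and ll[2] > ll[1]

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            window_likelihoods(0, 0)

    def test_n1_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            window_likelihoods(5, 4)


class TestPosterior:
    def test_all_parent1_calls_a(self):
        call, post = posterior_genotype(40, 40)
        assert call == A
        assert post.p_p1p1 > 0.999

    def test_half_calls_het(self):
        call, _ = posterior_genotype(20, 40)
        assert call == H

    def test_symmetric_errors_symmetric_posteriors(self):
        em = ErrorModel(0.03, 0.03)
        _, post = posterior_genotype(10, 20, em)
        assert post.p_p1p1 == pytest.approx(post.p_p2p2, rel=1e-12)

    def test_triple_sums_to_one(self):
        for n1 in range(0, 41, 5):
            _, post = posterior_genotype(n1, 40)
            assert post.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_n1(self):
        probs = [posterior_genotype(n1, 30)[1].p_p1p1 for n1 in range(31)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_matches_brute_force_small_n(self):
        for n in (1, 2, 4, 6):
            for n1 in range(n + 1):
                _, post = posterior_genotype(n1, n)
                expected = brute_force_posteriors(n1, n)
                np.testing.assert_allclose(
                    post.as_array(), [expected[0], expected[1], expected[2]], rtol=1e-10
                )

    def test_argmax_invariant_under_prior_rescaling(self):
        for n1 in (0, 13, 20, 40):
            c1, _ = posterior_genotype(n1, 40, priors=(0.25, 0.25, 0.5))
            c2, _ = posterior_genotype(n1, 40, priors=(2.5, 2.5, 5.0))
            assert c1 == c2


class TestSlideWindows:
    def _single_block(self, c1, c2):
        n_sites = c1.shape[0]
        positions = np.arange(n_sites) * 100
        blocks = np.zeros(n_sites, dtype=np.int64)
        return slide_windows(c1, c2, positions, blocks)

    def test_block_below_depth_floor_all_missing(self):
        c1 = np.full((13, 1), 3)  # total depth 39 < 40
        c2 = np.zeros((13, 1), dtype=int)
        out = self._single_block(c1, c2)
        assert (out == MISSING).all()

    def test_error_free_homozygote_all_a(self):
        c1 = np.full((20, 2), 5)
        c2 = np.zeros((20, 2), dtype=int)
        out = self._single_block(c1, c2)
        assert (out == A).all()

    def test_windows_do_not_cross_blocks(self):
        # two blocks, each with depth 39: both must stay missing even though
        # the combined depth would clear the floor
        c1 = np.full((26, 1), 3)
        c2 = np.zeros((26, 1), dtype=int)
        positions = np.arange(26) * 100
        blocks = np.concatenate([np.zeros(13, int), np.ones(13, int)])
        out = slide_windows(c1, c2, positions, blocks)
        assert (out == MISSING).all()

    def test_confidence_returned(self):
        c1 = np.full((20, 1), 5)
        c2 = np.zeros((20, 1), dtype=int)
        out, conf = slide_windows(
            c1, c2, np.arange(20) * 10, np.zeros(20, int), return_confidence=True
        )
        assert (out == A).all()
        assert (conf > 0.99).all()

    def test_improves_on_initial_for_simulated_cohort(self, small_cross, small_genotyped):
        idx, result = small_genotyped
        truth = small_cross.truth.genotypes[idx]

        def missing_and_accuracy(m):
            miss = m == MISSING
            return miss.mean(), (m[~miss] == truth[~miss]).mean()

        miss0, acc0 = missing_and_accuracy(result.initial)
        miss1, acc1 = missing_and_accuracy(result.imputed)
        assert miss1 < miss0
        assert acc1 > acc0


class TestConcordance:
    def test_perfect(self):
        g = np.array([[A, B], [H, H]], dtype=np.int8)
        rep = evaluate_concordance(
            g,
            np.array(["s", "s"]),
            np.array([100, 200]),
            [("s", 110, g[0]), ("s", 210, g[1])],
            flank_bp=20,
        )
        assert rep.accuracy == 1.0 and rep.missing_rate == 0.0

    def test_a_h_miscall_rate(self):
        truth_vec = np.array([A, A], dtype=np.int8)
        called = np.array([[A, H]], dtype=np.int8)
        rep = evaluate_concordance(
            called, np.array(["s"]), np.array([100]), [("s", 100, truth_vec)], 10
        )
        assert rep.a_h_miscall_rate == pytest.approx(0.5)
        assert rep.b_h_miscall_rate == 0.0

    def test_anchor_outside_flanks_errors(self):
        g = np.array([[A]], dtype=np.int8)
        with pytest.raises(ValueError, match="flank"):
            evaluate_concordance(
                g, np.array(["s"]), np.array([100]), [("s", 10_000, g[0])], 10
            )


class TestErrorModel:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ErrorModel(0.5, 0.02)
        with pytest.raises(ValueError):
            ErrorModel(0.058, -0.01)

    def test_het_p1_default(self):
        assert DEFAULTS.het_p1 == pytest.approx(0.481)


@settings(max_examples=50, deadline=None)
@given(
    n=st.integers(1, 60),
    frac=st.floats(0, 1),
    e1=st.floats(0, 0.4),
    e2=st.floats(0, 0.4),
)
def test_posterior_triple_always_normalized(n, frac, e1, e2):
    n1 = int(round(frac * n))
    _, post = posterior_genotype(n1, n, ErrorModel(e1, e2))
    assert post.as_array().sum() == pytest.approx(1.0, abs=1e-9)
    assert ((post.as_array() >= 0) & (post.as_array() <= 1)).all()
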