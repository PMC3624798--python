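"""Unit and property tests for the pairing model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairprob import (
    CandidateAlignment,
    CandidateSet,
    FragmentModel,
    GenomeInfo,
    PairParams,
    brute_force_posteriors,
    empty_mate_posteriors,
    mismap_to_mapq,
    pair_posteriors,
    pair_prior,
    score_to_odds,
)
from pairprob.fraglen import conjoint_fragment_length
from pairprob.model import cutoff_correction_mass, unmapped_records
from pairprob.types import MATE_FIRST, MATE_SECOND

from _instances import posteriors, random_instance


def aln(mate, chrom, strand, start, end, score, read_id="r"):
    return CandidateAlignment(read_id=read_id, mate=mate, chrom=chrom,
                              strand=strand, ref_start=start, ref_end=end,
                              score=score, read_span=(0, end - start),
                              read_length=end - start)


def cset(mate, *alns):
    return CandidateSet("r", mate, list(alns))


class TestScoreToOdds:
    def test_zero_score_is_unit_odds(self):
        assert score_to_odds(0, 3.7) == 1.0

    def test_score_of_T_ln2_doubles_the_odds(self):
        T = 4.0
        assert score_to_odds(T * math.log(2.0), T) == pytest.approx(2.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            score_to_odds(10, 0.0)

    def test_posteriors_invariant_to_overflow_shift(self, genome, normal_model):
        # shifting every score by a constant changes nothing but the shift
        rng = np.random.default_rng(7)
        for _ in range(20):
            A, B, params, model, g = random_instance(rng, max_side=8)
            shifted = PairParams(d=params.d, T=params.T, e=params.e + 5000,
                                 two_g=params.two_g,
                                 apply_cutoff_correction=params.apply_cutoff_correction)

            def bump(S):
                return CandidateSet(S.read_id, S.mate, [
                    CandidateAlignment(read_id=a.read_id, mate=a.mate,
                                       chrom=a.chrom, strand=a.strand,
                                       ref_start=a.ref_start, ref_end=a.ref_end,
                                       score=a.score + 5000,
                                       read_span=a.read_span,
                                       read_length=a.read_length)
                    for a in S])

            base = pair_posteriors(A, B, params, model, g)
            moved = pair_posteriors(bump(A), bump(B), shifted, model, g)
            for side in (0, 1):
                np.testing.assert_allclose(posteriors(base[side]),
                                           posteriors(moved[side]), rtol=1e-12)


class TestFragmentLength:
    def test_convention_forward_start_to_reverse_end(self, genome):
        a = aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30)
        b = aln(MATE_SECOND, "chr1", "-", 1300, 1400, 30)
        assert conjoint_fragment_length(a, b, genome) == 400

    def test_different_chromosomes_incompatible(self, genome):
        a = aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30)
        b = aln(MATE_SECOND, "chr7", "-", 1300, 1400, 30)
        assert conjoint_fragment_length(a, b, genome) is None

    def test_same_strand_incompatible(self, genome):
        a = aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30)
        b = aln(MATE_SECOND, "chr1", "+", 1300, 1400, 30)
        assert conjoint_fragment_length(a, b, genome) is None

    def test_negative_and_unbounded_lengths_allowed(self, genome):
        a = aln(MATE_FIRST, "chr1", "+", 5000, 5100, 30)
        b = aln(MATE_SECOND, "chr1", "-", 1300, 1400, 30)
        assert conjoint_fragment_length(a, b, genome) == 1400 - 5000

    def test_circular_wrap_maximizes_density(self):
        genome = GenomeInfo({"chrM": 1000}, {"chrM": True})
        model = FragmentModel("normal", 200.0, 30.0)
        a = aln(MATE_FIRST, "chrM", "+", 900, 950, 30)
        b = aln(MATE_SECOND, "chrM", "-", 50, 100, 30)
        # raw f = -800; wrapping by +L gives 200, at the model's mode
        assert conjoint_fragment_length(a, b, genome, model) == 200

    def test_unknown_chromosome_is_an_error(self, genome):
        a = aln(MATE_FIRST, "chrZ", "+", 0, 100, 30)
        b = aln(MATE_SECOND, "chrZ", "-", 300, 400, 30)
        with pytest.raises(KeyError):
            conjoint_fragment_length(a, b, genome)


class TestPairPrior:
    def test_zero_d_kills_disjoint_term(self, normal_model, params_factory):
        assert pair_prior(123, False, params_factory(d=0.0), normal_model) == 0.0

    def test_incompatible_pair_has_zero_conjoint_prior(self, normal_model,
                                                       params_factory):
        assert pair_prior(None, True, params_factory(), normal_model) == 0.0

    def test_conjoint_prior_at_mode_closed_form(self, params_factory):
        model = FragmentModel("normal", 400.0, 50.0)
        params = params_factory(d=0.01, two_g=2_000_000)
        pi_max = 1.0 / (50.0 * math.sqrt(2 * math.pi))
        expected = 0.99 * pi_max / 2e6
        assert pair_prior(400, True, params, model) == pytest.approx(expected,
                                                                     rel=1e-12)


class TestPairPosteriors:
    def test_single_conjoint_pair_is_certain_when_d_zero(self, genome,
                                                         normal_model,
                                                         params_factory):
        A = cset(MATE_FIRST, aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30))
        B = cset(MATE_SECOND, aln(MATE_SECOND, "chr1", "-", 1300, 1400, 30))
        ra, rb = pair_posteriors(A, B, params_factory(d=0.0), normal_model, genome)
        assert ra[0].posterior == pytest.approx(1.0)
        assert rb[0].posterior == pytest.approx(1.0)

    def test_d_one_equal_scores_split_evenly(self, genome, normal_model,
                                             params_factory):
        A = cset(MATE_FIRST,
                 aln(MATE_FIRST, "chr1", "+", 1000, 1100, 10),
                 aln(MATE_FIRST, "chr7", "+", 5000, 5100, 10))
        B = cset(MATE_SECOND, aln(MATE_SECOND, "chr1", "-", 1300, 1400, 25))
        ra, _ = pair_posteriors(A, B, params_factory(d=1.0), normal_model, genome)
        assert posteriors(ra) == pytest.approx([0.5, 0.5])

    def test_d_one_reduces_to_score_softmax(self, genome, normal_model,
                                            params_factory):
        scores = [30, 25, 18]
        T = 4.0
        A = cset(MATE_FIRST, *[
            aln(MATE_FIRST, "chr1", "+", 1000 * (i + 1), 1000 * (i + 1) + 100, s)
            for i, s in enumerate(scores)])
        B = cset(MATE_SECOND, aln(MATE_SECOND, "chr1", "-", 1300, 1400, 25))
        ra, _ = pair_posteriors(A, B, params_factory(d=1.0, T=T), normal_model,
                                genome)
        w = np.exp(np.array(scores) / T)
        np.testing.assert_allclose(posteriors(ra), w / w.sum(), rtol=1e-12)

    def test_reference_instance_matches_oracle(self, genome, normal_model,
                                               params_factory):
        A = cset(MATE_FIRST,
                 aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30),
                 aln(MATE_FIRST, "chr7", "+", 5000, 5100, 25))
        B = cset(MATE_SECOND, aln(MATE_SECOND, "chr1", "-", 1300, 1400, 30))
        params = params_factory(d=0.01, T=4.0, two_g=2_000_000)
        ra, rb = pair_posteriors(A, B, params, normal_model, genome)
        ba, bb = brute_force_posteriors(A, B, params, normal_model, genome)
        np.testing.assert_allclose(posteriors(ra), posteriors(ba), rtol=1e-12)
        np.testing.assert_allclose(posteriors(rb), posteriors(bb), rtol=1e-12)
        # the conjoint candidate dominates its disjoint competitor
        assert ra[0].posterior > 0.999

    def test_raising_a_score_raises_its_posterior(self, rng):
        for _ in range(25):
            A, B, params, model, genome = random_instance(rng, max_side=6)
            if len(A) < 2:
                continue
            ra, _ = pair_posteriors(A, B, params, model, genome)
            if ra[0].posterior == 0.0 or ra[0].posterior >= 1.0 - 1e-15:
                continue  # degenerate: no admissible competition
            boosted = CandidateSet(A.read_id, A.mate, [
                CandidateAlignment(read_id=a.read_id, mate=a.mate, chrom=a.chrom,
                                   strand=a.strand, ref_start=a.ref_start,
                                   ref_end=a.ref_end,
                                   score=a.score + (15 if i == 0 else 0),
                                   read_span=a.read_span,
                                   read_length=a.read_length)
                for i, a in enumerate(A)])
            rb, _ = pair_posteriors(boosted, B, params, model, genome)
            assert rb[0].posterior > ra[0].posterior

    def test_conjoint_mate_at_mode_boosts_posterior(self, genome, normal_model,
                                                    params_factory):
        A = cset(MATE_FIRST,
                 aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30),
                 aln(MATE_FIRST, "chr7", "+", 5000, 5100, 30))
        B_far = cset(MATE_SECOND, aln(MATE_SECOND, "chr7", "-", 900000, 900100, 20))
        params = params_factory(d=0.5)
        base, _ = pair_posteriors(A, B_far, params, normal_model, genome)
        # add a mate candidate conjoint with A[0] at the fragment mode
        B_near = cset(MATE_SECOND,
                      B_far.alignments[0],
                      aln(MATE_SECOND, "chr1", "-", 1300, 1400, 20))
        near, _ = pair_posteriors(A, B_near, params, normal_model, genome)
        assert near[0].posterior > base[0].posterior

    def test_at_most_one_confident_candidate_per_read(self, rng):
        for _ in range(200):
            A, B, params, model, genome = random_instance(rng, max_side=10)
            ra, rb = pair_posteriors(A, B, params, model, genome)
            for side in (ra, rb):
                assert sum(r.mismap < 0.5 for r in side) <= 1

    def test_circular_origin_translation_invariance(self):
        genome = GenomeInfo({"chrM": 16000}, {"chrM": True})
        model = FragmentModel("normal", 400.0, 50.0)
        params = PairParams(d=0.01, T=4.0, e=0, two_g=genome.two_g,
                            apply_cutoff_correction=True)

        def instance(offset):
            L = 16000
            # a conjoint pair near the origin, translated around the circle
            s1, e1 = (15700 + offset) % L, (15700 + offset) % L + 100
            s2, e2 = (16000 + offset) % L, (16000 + offset) % L + 100
            A = cset(MATE_FIRST, aln(MATE_FIRST, "chrM", "+", s1, e1, 30))
            B = cset(MATE_SECOND, aln(MATE_SECOND, "chrM", "-", s2, e2, 30))
            decoyA = aln(MATE_FIRST, "chrM", "+", (5000 + offset) % L,
                         (5000 + offset) % L + 100, 28)
            A = cset(MATE_FIRST, A.alignments[0], decoyA)
            return pair_posteriors(A, B, params, model, genome)

        base = instance(0)
        for offset in (100, 5000, 15900):
            moved = instance(offset)
            for side in (0, 1):
                np.testing.assert_allclose(posteriors(base[side]),
                                           posteriors(moved[side]), atol=1e-9)


class TestOracleEquivalence:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_factorized_equals_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        A, B, params, model, genome = random_instance(rng)
        fa, fb = pair_posteriors(A, B, params, model, genome)
        ba, bb = brute_force_posteriors(A, B, params, model, genome)
        np.testing.assert_allclose(posteriors(fa), posteriors(ba),
                                   rtol=1e-12, atol=1e-200)
        np.testing.assert_allclose(posteriors(fb), posteriors(bb),
                                   rtol=1e-12, atol=1e-200)

    def test_brute_force_refuses_large_instances(self, genome, normal_model,
                                                 params_factory):
        A = cset(MATE_FIRST, *[aln(MATE_FIRST, "chr1", "+", 100 * i, 100 * i + 50, 20)
                               for i in range(1, 120)])
        B = cset(MATE_SECOND, *[aln(MATE_SECOND, "chr1", "-", 100 * i, 100 * i + 50, 20)
                                for i in range(1, 120)])
        with pytest.raises(ValueError):
            brute_force_posteriors(A, B, params_factory(), normal_model, genome)


class TestNormalization:
    def test_sums_to_one_without_correction(self, rng):
        for _ in range(100):
            A, B, params, model, genome = random_instance(rng)
            params = PairParams(d=max(params.d, 1e-3), T=params.T, e=params.e,
                                two_g=params.two_g, apply_cutoff_correction=False)
            ra, rb = pair_posteriors(A, B, params, model, genome)
            assert sum(posteriors(ra)) == pytest.approx(1.0, abs=1e-9)
            assert sum(posteriors(rb)) == pytest.approx(1.0, abs=1e-9)

    def test_correction_mass_completes_the_total(self, rng):
        # independent recomputation of N(a), Y and w with plain numpy
        for _ in range(100):
            A, B, params, model, genome = random_instance(rng)
            params = PairParams(d=max(params.d, 1e-3), T=params.T, e=params.e,
                                two_g=params.two_g, apply_cutoff_correction=True)
            ra, _ = pair_posteriors(A, B, params, model, genome)
            T, d, two_g = params.T, params.d, params.two_g
            shift_a = max(max(a.score for a in A), params.e - 1)
            shift_b = max(b.score for b in B)
            eb = np.exp((np.array([b.score for b in B]) - shift_b) / T)
            Y = eb.sum()
            N = []
            for a in A:
                c = sum(w_b * model.density(f)
                        for b, w_b in zip(B, eb)
                        if (f := conjoint_fragment_length(a, b, genome, model))
                        is not None)
                N.append(math.exp((a.score - shift_a) / T)
                         * ((1 - d) * two_g * c + d * Y))
            w = cutoff_correction_mass(params, model, Y, shift_a, shift_b)
            Z = sum(N) + w
            total = sum(posteriors(ra))
            assert total + w / Z == pytest.approx(1.0, abs=1e-9)
            if w / Z > 1e-12:  # correction mass can underflow to nothing
                assert total < 1.0


class TestCutoffCorrection:
    def test_correction_vanishes_as_cutoff_drops(self, genome, normal_model):
        A = cset(MATE_FIRST, aln(MATE_FIRST, "chr1", "+", 1000, 1100, 30))
        B = cset(MATE_SECOND, aln(MATE_SECOND, "chr1", "-", 1300, 1400, 30))
        base = pair_posteriors(A, B, PairParams(0.01, 4.0, 10, genome.two_g,
                                                False), normal_model, genome)
        low = pair_posteriors(A, B, PairParams(0.01, 4.0, -2000, genome.two_g,
                                               True), normal_model, genome)
        np.testing.assert_allclose(posteriors(low[0]), posteriors(base[0]),
                                   atol=1e-12)

    def test_unlucky_case_demotes_random_alignment(self, genome, normal_model):
        # read 1's only surviving alignment is a random hit at the cutoff;
        # read 2 maps uniquely and far from it
        e = 100
        A = cset(MATE_FIRST, aln(MATE_FIRST, "chr7", "+", 600_000, 600_100, e))
        B = cset(MATE_SECOND, aln(MATE_SECOND, "chr1", "-", 1300, 1400, e + 80))
        off = pair_posteriors(A, B, PairParams(0.01, 4.0, e, genome.two_g,
                                               False), normal_model, genome)
        on = pair_posteriors(A, B, PairParams(0.01, 4.0, e, genome.two_g,
                                              True), normal_model, genome)
        assert off[0][0].posterior == pytest.approx(1.0)
        assert on[0][0].posterior < 0.5  # the hidden true alignment wins


class TestEmptyMate:
    def test_softmax_without_correction(self, normal_model, params_factory):
        A = cset(MATE_FIRST,
                 aln(MATE_FIRST, "chr1", "+", 1000, 1100, 20),
                 aln(MATE_FIRST, "chr7", "+", 2000, 2100, 20))
        recs = empty_mate_posteriors(A, params_factory(correction=False),
                                     normal_model)
        assert posteriors(recs) == pytest.approx([0.5, 0.5])

    def test_single_candidate_certain_without_correction(self, normal_model,
                                                         params_factory):
        A = cset(MATE_FIRST, aln(MATE_FIRST, "chr1", "+", 1000, 1100, 20))
        recs = empty_mate_posteriors(A, params_factory(correction=False),
                                     normal_model)
        assert recs[0].posterior == pytest.approx(1.0)

    def test_closed_form_with_correction(self, normal_model):
        d, T, e, two_g = 0.01, 4.0, 17, 2_000_000
        params = PairParams(d, T, e, two_g, apply_cutoff_correction=True)
        A = cset(MATE_FIRST, aln(MATE_FIRST, "chr1", "+", 1000, 1100, e))
        recs = empty_mate_posteriors(A, params, normal_model)
        pi_max = 1.0 / (50.0 * math.sqrt(2 * math.pi))
        num = math.exp(e / T) * d
        den = num + math.exp((e - 1) / T) * ((1 - d) * two_g * pi_max + d)
        assert recs[0].posterior == pytest.approx(num / den, rel=1e-12)

    def test_routed_from_pair_posteriors(self, genome, normal_model,
                                         params_factory):
        A = cset(MATE_FIRST, aln(MATE_FIRST, "chr1", "+", 1000, 1100, 20))
        B = CandidateSet("r", MATE_SECOND, [])
        ra, rb = pair_posteriors(A, B, params_factory(correction=False),
                                 normal_model, genome)
        assert rb == []
        assert ra[0].posterior == pytest.approx(1.0)

    def test_both_empty_yields_explicit_unmapped(self, genome, normal_model,
                                                 params_factory):
        A = CandidateSet("r", MATE_FIRST, [])
        B = CandidateSet("r", MATE_SECOND, [])
        ra, rb = pair_posteriors(A, B, params_factory(), normal_model, genome)
        assert ra[0].is_unmapped and rb[0].is_unmapped
        assert unmapped_records(A, B)[0].mismap == 1.0


class TestMapq:
    @pytest.mark.parametrize("p, cap, expected", [
        (0.1, 60, 10),
        (1.0, 60, 0),
        (1e-7, 60, 60),
        (0.0, 60, 60),
        (0.01, 37, 20),
    ])
    def test_phred_scaling_and_clamp(self, p, cap, expected):
        assert mismap_to_mapq(p, cap) == expected

    def test_rejects_improper_probability(self):
        with pytest.raises(ValueError):
            mismap_to_mapq(1.5)
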