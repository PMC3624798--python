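"""The Bayesian pairing model.

Each read of a pair (alpha, beta) has a set of candidate local alignments
(A, B) whose integer scores are scaled log-likelihood ratios:
exp(s/T) is proportional to P(read | alignment is the source).  The prior
over a joint placement (a, b) is

    I = 0 (disjoint):  d / (2g)^2
    I = 1 (conjoint):  (1 - d) * pi(f_ab) / (2g)      (0 if incompatible)

where d is the prior disjoint probability, 2g the number of bases in both
strands of the haploid genome, and pi the fitted fragment-length density.
The marginal posterior that candidate a is the true source of alpha is the
sum over b and I of likelihood x prior, normalised over A.  Working with
priors scaled by (2g)^2, the numerator factorises as

    N(a) = exp(s_a/T) * [ (1-d) * 2g * c(a) + d * Y ]
    c(a) = sum_{b conjoint with a} exp(s_b/T) * pi(f_ab)
    Y    = sum_{b in B} exp(s_b/T)

and posterior(a) = N(a) / (sum_a' N(a') + w), where w is an optional
correction for the aligner's score cutoff e: an "unlucky" hypothetical
alignment of this read with score e-1 (the highest integer score below the
cutoff), sitting at the optimal fragment distance from the mate's best
alignment,

    w = exp((e-1)/T) * [ (1-d) * 2g * pi_max * exp(s_B_max/T) + d * Y ].

All exponentials are computed with a per-read shift (the maximum relevant
score) so only ratios matter and overflow cannot occur.
"""

from __future__ import annotations

import math
from typing import Optional

from .fraglen import FragmentModel, conjoint_fragment_length
from .types import (
    CandidateAlignment,
    CandidateSet,
    GenomeInfo,
    PairParams,
    PosteriorRecord,
)

DEFAULT_MAPQ_CAP = 60


def score_to_odds(score: float, T: float, shift: float = 0.0) -> float:
    """exp((score - shift) / T): the likelihood ratio encoded by a score.

    The optional shift guards against overflow; posteriors are invariant to
    it because only ratios of these values enter the model.
    """
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return math.exp((score - shift) / T)


def mismap_to_mapq(p: float, cap: int = DEFAULT_MAPQ_CAP) -> int:
    """Phred-scale a mismap probability: round(-10 log10 p), clamped to [0, cap]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mismap probability must be in [0, 1], got {p}")
    if p == 0.0:
        return cap
    q = round(-10.0 * math.log10(p))
    return int(min(max(q, 0), cap))


def _record(aln: CandidateAlignment, posterior: float, cap: int) -> PosteriorRecord:
    posterior = min(max(posterior, 0.0), 1.0)
    mismap = 1.0 - posterior
    return PosteriorRecord(
        read_id=aln.read_id,
        mate=aln.mate,
        alignment=aln,
        posterior=posterior,
        mismap=mismap,
        mapq=mismap_to_mapq(mismap, cap),
    )


def pair_prior(
    f: Optional[int],
    conjoint: bool,
    params: PairParams,
    model: FragmentModel,
) -> float:
    """Prior probability of a joint placement with fragment length f.

    ``f`` is None for an incompatible pair (different chromosome or same
    strand), which has zero conjoint prior.
    """
    two_g = params.two_g
    if not conjoint:
        return params.d / (two_g * two_g)
    if f is None:
        return 0.0
    return (1.0 - params.d) * float(model.density(f)) / two_g


def _side_posteriors(
    A: CandidateSet,
    B: CandidateSet,
    params: PairParams,
    model: FragmentModel,
    genome: GenomeInfo,
    mapq_cap: int,
) -> list[PosteriorRecord]:
    """Posteriors for the candidates of A given the mate's candidates B."""
    T = params.T
    shift_a = max(max(a.score for a in A), params.e - 1)
    shift_b = max(b.score for b in B)
    eb = [score_to_odds(b.score, T, shift_b) for b in B]
    Y = sum(eb)
    one_minus_d_2g = (1.0 - params.d) * params.two_g

    numerators = []
    for a in A:
        c = 0.0
        for b, wb in zip(B, eb):
            f = conjoint_fragment_length(a, b, genome, model)
            if f is not None:
                c += wb * float(model.density(f))
        numerators.append(
            score_to_odds(a.score, T, shift_a) * (one_minus_d_2g * c + params.d * Y)
        )

    Z = sum(numerators)
    if params.apply_cutoff_correction:
        Z += cutoff_correction_mass(params, model, Y=Y, shift_a=shift_a, shift_b=shift_b)
    if Z == 0.0:
        # degenerate: d == 0 and no conjoint geometry anywhere
        return [_record(a, 0.0, mapq_cap) for a in A]
    return [_record(a, n / Z, mapq_cap) for a, n in zip(A, numerators)]


def cutoff_correction_mass(
    params: PairParams,
    model: FragmentModel,
    Y: float,
    shift_a: float = 0.0,
    shift_b: float = 0.0,
) -> float:
    """Denominator mass of the hypothetical sub-cutoff alignment (score e-1).

    ``Y`` must be computed with the same ``shift_b`` and ``shift_b`` must be
    the mate's maximum score, so that the conjoint part
    pi_max * exp(s_B_max/T) reduces to pi_max under the shift.
    """
    w_hyp = score_to_odds(params.e - 1, params.T, shift_a)
    conjoint = (1.0 - params.d) * params.two_g * model.density_max  # exp term = 1
    return w_hyp * (conjoint + params.d * Y)


def empty_mate_posteriors(
    A: CandidateSet,
    params: PairParams,
    model: FragmentModel,
    mapq_cap: int = DEFAULT_MAPQ_CAP,
) -> list[PosteriorRecord]:
    """Posteriors when the mate has no candidate alignments at all.

    Treated as if the mate had a single alignment on a different chromosome
    from every candidate in A; its score factor cancels from every term and
    never needs to be specified.  Without the cutoff correction this is the
    within-read score softmax.
    """
    if A.is_empty:
        return []
    T = params.T
    shift = max(max(a.score for a in A), params.e - 1)
    ea = [score_to_odds(a.score, T, shift) for a in A]
    if not params.apply_cutoff_correction:
        total = sum(ea)
        return [_record(a, w / total, mapq_cap) for a, w in zip(A, ea)]
    numerators = [params.d * w for w in ea]
    w_hyp = score_to_odds(params.e - 1, T, shift) * (
        (1.0 - params.d) * params.two_g * model.density_max + params.d
    )
    Z = sum(numerators) + w_hyp
    return [_record(a, n / Z, mapq_cap) for a, n in zip(A, numerators)]


def unmapped_records(A: CandidateSet, B: CandidateSet) -> list[PosteriorRecord]:
    """Explicit unmapped records for a pair with no candidates on either end."""
    return [
        PosteriorRecord(read_id=S.read_id, mate=S.mate, alignment=None,
                        posterior=0.0, mismap=1.0, mapq=0)
        for S in (A, B)
    ]


def pair_posteriors(
    A: CandidateSet,
    B: CandidateSet,
    params: PairParams,
    model: FragmentModel,
    genome: GenomeInfo,
    mapq_cap: int = DEFAULT_MAPQ_CAP,
) -> tuple[list[PosteriorRecord], list[PosteriorRecord]]:
    """Marginal posteriors for every candidate of both reads of a pair.

    Empty candidate sets are handled by the empty-mate rule; a pair with no
    candidates on either end yields explicit unmapped records.
    """
    if model is None:
        raise ValueError("a fitted FragmentModel is required")
    if A.is_empty and B.is_empty:
        recs = unmapped_records(A, B)
        return [recs[0]], [recs[1]]
    if B.is_empty:
        return empty_mate_posteriors(A, params, model, mapq_cap), []
    if A.is_empty:
        return [], empty_mate_posteriors(B, params, model, mapq_cap)
    rec_a = _side_posteriors(A, B, params, model, genome, mapq_cap)
    rec_b = _side_posteriors(B, A, params, model, genome, mapq_cap)
    return rec_a, rec_b


def brute_force_posteriors(
    A: CandidateSet,
    B: CandidateSet,
    params: PairParams,
    model: FragmentModel,
    genome: GenomeInfo,
    mapq_cap: int = DEFAULT_MAPQ_CAP,
    max_terms: int = 10_000,
) -> tuple[list[PosteriorRecord], list[PosteriorRecord]]:
    """Reference computation by the explicit double sum over (a, b, I).

    Test oracle only: O(|A| x |B|) per candidate side, refuses large
    instances.  The cutoff correction enters as one extra outcome per side:
    a hypothetical alignment with score e-1 conjoint at the optimal
    distance with the mate's best alignment.
    """
    if len(A) * len(B) > max_terms:
        raise ValueError(f"instance too large for brute force ({len(A)}x{len(B)})")
    if A.is_empty or B.is_empty:
        # same routing as the production path
        return pair_posteriors(A, B, params, model, genome, mapq_cap)

    scale = float(params.two_g) ** 2  # priors scaled by (2g)^2 throughout

    def side(X: CandidateSet, M: CandidateSet) -> list[PosteriorRecord]:
        shift_x = max(max(x.score for x in X), params.e - 1)
        shift_m = max(m.score for m in M)

        def mass(x: CandidateAlignment) -> float:
            total = 0.0
            for m in M:
                lik = score_to_odds(x.score, params.T, shift_x) * score_to_odds(
                    m.score, params.T, shift_m
                )
                f = conjoint_fragment_length(x, m, genome, model)
                total += lik * pair_prior(f, True, params, model) * scale
                total += lik * pair_prior(None, False, params, model) * scale
            return total

        numerators = [mass(x) for x in X]
        Z = sum(numerators)
        if params.apply_cutoff_correction:
            hyp_lik = score_to_odds(params.e - 1, params.T, shift_x)
            best = max(m.score for m in M)
            # conjoint with the best mate alignment at the optimal distance
            Z += (
                hyp_lik
                * score_to_odds(best, params.T, shift_m)
                * (1.0 - params.d)
                * model.density_max
                / params.two_g
                * scale
            )
            for m in M:
                Z += (
                    hyp_lik
                    * score_to_odds(m.score, params.T, shift_m)
                    * pair_prior(None, False, params, model)
                    * scale
                )
        if Z == 0.0:
            return [_record(x, 0.0, mapq_cap) for x in X]
        return [_record(x, n / Z, mapq_cap) for x, n in zip(X, numerators)]

    return side(A, B), side(B, A)
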