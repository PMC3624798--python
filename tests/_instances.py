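"""Random problem-instance generation shared by the model tests."""

from __future__ import annotations

import numpy as np

from pairprob import (
    CandidateAlignment,
    CandidateSet,
    FragmentModel,
    GenomeInfo,
    PairParams,
)
from pairprob.types import MATE_FIRST, MATE_SECOND


def random_instance(rng: np.random.Generator, max_side: int = 20,
                    allow_circular: bool = True):
    """A random (A, B, params, model, genome) pairing problem.

    Candidate coordinates, strands and chromosomes are arbitrary; scores sit
    at or above the cutoff; d, T and the fragment model vary over wide
    ranges so the factorized computation is exercised across regimes.
    """
    n_chrom = int(rng.integers(1, 4))
    lengths = {f"c{i}": int(rng.integers(5_000, 200_000)) for i in range(n_chrom)}
    circular = {name: bool(allow_circular and rng.random() < 0.3)
                for name in lengths}
    genome = GenomeInfo(lengths, circular)

    if rng.random() < 0.2:
        model = FragmentModel("lognormal", float(rng.uniform(4.0, 7.0)),
                              float(rng.uniform(0.1, 0.8)))
    else:
        model = FragmentModel("normal", float(rng.uniform(100, 800)),
                              float(rng.uniform(10, 120)))

    e = int(rng.integers(-50, 100))
    params = PairParams(
        d=float(rng.choice([0.0, 1.0, rng.uniform(0.0, 1.0)],
                           p=[0.1, 0.1, 0.8])),
        T=float(rng.uniform(1.0, 10.0)),
        e=e,
        two_g=genome.two_g,
        apply_cutoff_correction=bool(rng.random() < 0.5),
    )

    def side(mate: str, n: int) -> CandidateSet:
        alns = []
        for _ in range(n):
            chrom = f"c{rng.integers(n_chrom)}"
            L = lengths[chrom]
            size = int(rng.integers(20, 150))
            start = int(rng.integers(0, max(L - size, 1)))
            alns.append(CandidateAlignment(
                read_id="r", mate=mate, chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                ref_start=start, ref_end=start + size,
                score=int(rng.integers(e, e + 120)),
                read_span=(0, size), read_length=size,
            ))
        return CandidateSet("r", mate, alns)

    A = side(MATE_FIRST, int(rng.integers(1, max_side + 1)))
    B = side(MATE_SECOND, int(rng.integers(1, max_side + 1)))
    return A, B, params, model, genome


def posteriors(records) -> list[float]:
    return [r.posterior for r in records]


def independent_side_mass(A, B, params, model, genome):
    """Recompute N(a), w and Z for side A with plain numpy (test oracle)."""
    import math

    from pairprob.fraglen import conjoint_fragment_length
    from pairprob.model import cutoff_correction_mass

    T, d, two_g = params.T, params.d, params.two_g
    shift_a = max(max(a.score for a in A), params.e - 1)
    shift_b = max(b.score for b in B)
    eb = np.exp((np.array([b.score for b in B]) - shift_b) / T)
    Y = float(eb.sum())
    N = []
    for a in A:
        c = 0.0
        for b, w_b in zip(B, eb):
            f = conjoint_fragment_length(a, b, genome, model)
            if f is not None:
                c += w_b * float(model.density(f))
        N.append(math.exp((a.score - shift_a) / T)
                 * ((1 - d) * two_g * c + d * Y))
    w = cutoff_correction_mass(params, model, Y, shift_a, shift_b)
    Z = sum(N) + (w if params.apply_cutoff_correction else 0.0)
    return N, w, Z
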