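"""Synthetic paired-end data generation.

The generator emulates a full simulation workflow at toy scale: a random
genome, a diploid copy with SNPs, fragments drawn from a fragment-length
model, reads with per-base errors drawn from a position x phred quality
profile, optional shuffling of one FASTQ to create disjoint pairs, and
candidate alignment sets with a known score scale, bypassing the alignment
phase so the pairing model is testable without an aligner.

Candidate scores are generated so that they really are scaled
log-likelihood ratios, which the pairing model assumes.  Decoy scores are
drawn from a discrete Gaussian on the integers (the "noise" distribution);
true-alignment scores are drawn from its exponential tilt by exp(s/T),
which for a discrete Gaussian is the same distribution shifted up by
sigma^2/T.  With this construction the model's posterior is the exact
Bayes posterior of the generative process, so posterior calibration can be
tested rather than assumed.  Decoys land at uniform genomic positions and
score below true alignments on average (the tilt shift is a few noise
standard deviations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .fraglen import FragmentModel
from .types import (
    MATE_FIRST,
    MATE_SECOND,
    CandidateAlignment,
    CandidateSet,
    GenomeInfo,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
_OTHER = {b: BASES.replace(b, "") for b in BASES}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# truth table

@dataclass(frozen=True)
class TruthRecord:
    """True genomic source of one simulated read."""

    read_id: str
    mate: str
    chrom: str
    strand: str
    start: int
    end: int
    conjoint: bool
    fragment_length: int


TRUTH_COLUMNS = ["read_id", "mate", "chrom", "strand", "start", "end",
                 "conjoint", "fragment_length"]


def write_truth(truth_pairs: Iterable[tuple[TruthRecord, TruthRecord]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for pair in truth_pairs:
            for t in pair:
                fh.write(
                    f"{t.read_id}\t{t.mate}\t{t.chrom}\t{t.strand}\t{t.start}\t"
                    f"{t.end}\t{int(t.conjoint)}\t{t.fragment_length}\n"
                )


def read_truth(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth table header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(TruthRecord(f[0], f[1], f[2], f[3], int(f[4]), int(f[5]),
                                   bool(int(f[6])), int(f[7])))
    return out


# ---------------------------------------------------------------------------
# quality profile

@dataclass
class QualityProfile:
    """Per-position distribution over phred quality scores.

    ``probs`` has shape (read_length, len(levels)); each row sums to 1.
    """

    levels: np.ndarray  # integer phred values
    probs: np.ndarray   # (read_len, n_levels)

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each position's quality distribution must sum to 1")

    @property
    def read_length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def illumina_like(cls, read_length: int, q_start: float = 38.0,
                      q_end: float = 30.0, spread: float = 3.0) -> "QualityProfile":
        """A smooth profile with quality degrading toward the 3' end.

        Mimics the shape of empirical profiles: high, tight qualities at
        the 5' end and a broader, lower distribution near the 3' end.
        """
        levels = np.arange(2, 42)
        pos = np.linspace(0.0, 1.0, read_length)
        means = q_start - (q_start - q_end) * pos**1.5
        z = (levels[None, :] - means[:, None]) / spread
        probs = np.exp(-0.5 * z * z)
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(levels=levels, probs=probs)

    @classmethod
    def constant(cls, read_length: int, q: int) -> "QualityProfile":
        levels = np.array([q])
        return cls(levels=levels, probs=np.ones((read_length, 1)))

    def sample(self, n_reads: int, rng: np.random.Generator) -> np.ndarray:
        """(n_reads, read_length) matrix of phred scores."""
        out = np.empty((n_reads, self.read_length), dtype=np.int64)
        for j in range(self.read_length):
            out[:, j] = rng.choice(self.levels, size=n_reads, p=self.probs[j])
        return out


# ---------------------------------------------------------------------------
# scoring model

@dataclass
class ScoringModel:
    """Substitution scoring scheme with a known scale factor T.

    Scores are integers S_xy = round(T * ln(M_xy / (A_x * B_y))) where A
    and B are background base abundances and M is the aligned-pair joint
    probability; a score is therefore T times a natural-log likelihood
    ratio, rounded.
    """

    S: np.ndarray           # (4, 4) integer scores
    A: np.ndarray           # reference base abundances
    B: np.ndarray           # query base abundances
    M: np.ndarray           # aligned-pair joint probabilities
    T: float
    score_sd: float = 15.0  # spread of candidate alignment scores

    @classmethod
    def from_error_rate(cls, error_rate: float = 0.01, T: float = 5.0,
                        score_sd: float = 15.0) -> "ScoringModel":
        A = np.full(4, 0.25)
        B = np.full(4, 0.25)
        M = np.full((4, 4), error_rate / 12.0)
        np.fill_diagonal(M, (1.0 - error_rate) / 4.0)
        S = np.rint(T * np.log(M / np.outer(A, B))).astype(int)
        return cls(S=S, A=A, B=B, M=M, T=T, score_sd=score_sd)

    def expected_score(self, n_aligned: int) -> float:
        """Expected score of a true gapless alignment of n_aligned bases."""
        return float(n_aligned * (self.M * self.S).sum())


def _discrete_gaussian(center: float, sd: float,
                       lower: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of a Gaussian restricted to the integer lattice."""
    lo = math.floor(center - 8.0 * sd)
    hi = math.ceil(center + 8.0 * sd)
    if lower is not None:
        lo = max(lo, lower)
    support = np.arange(lo, hi + 1)
    if support.size == 0:
        raise ValueError("empty score support; cutoff too high for the model")
    logp = -0.5 * ((support - center) / sd) ** 2
    p = np.exp(logp - logp.max())
    return support, p / p.sum()


# ---------------------------------------------------------------------------
# genome and reads

def make_genome(lengths: Sequence[int], gc: float = 0.41, seed: int = 0,
                circular: Iterable[str] = (),
                names: Optional[Sequence[str]] = None) -> tuple[dict[str, str], GenomeInfo]:
    """Random genome with the given chromosome lengths and GC content."""
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(lengths))]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seqs = {}
    for name, length in zip(names, lengths):
        idx = rng.choice(4, size=length, p=p)
        seqs[name] = "".join(BASES[i] for i in idx)
    circ = set(circular)
    info = GenomeInfo({n: len(s) for n, s in seqs.items()},
                      {n: n in circ for n in seqs})
    return seqs, info


def make_diploid(genome: dict[str, str], snp_rate: float, seed: int = 0,
                 ) -> tuple[list[dict[str, str]], list[tuple[str, int, int, str, str]]]:
    """Two haplotypes with independent per-site SNPs at ``snp_rate``.

    Returns (haplotypes, variants); each variant is
    (chrom, position, haplotype index, ref base, alt base).
    """
    if not 0.0 <= snp_rate <= 0.1:
        raise ValueError("snp_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    haplotypes = []
    variants: list[tuple[str, int, int, str, str]] = []
    for h in range(2):
        hap = {}
        for chrom, seq in genome.items():
            arr = list(seq)
            n_mut = rng.binomial(len(seq), snp_rate)
            sites = rng.choice(len(seq), size=n_mut, replace=False)
            for pos in sorted(sites):
                ref = arr[pos]
                alt = _OTHER[ref][rng.integers(3)]
                arr[pos] = alt
                variants.append((chrom, int(pos), h, ref, alt))
            hap[chrom] = "".join(arr)
        haplotypes.append(hap)
    return haplotypes, variants


def apply_variants(genome: dict[str, str],
                   variants: Iterable[tuple[str, int, int, str, str]],
                   haplotype: int) -> dict[str, str]:
    """Reconstruct one haplotype from the reference and a variant table."""
    arrs = {chrom: list(seq) for chrom, seq in genome.items()}
    for chrom, pos, h, ref, alt in variants:
        if h != haplotype:
            continue
        if arrs[chrom][pos] != ref:
            raise ValueError(f"variant ref mismatch at {chrom}:{pos}")
        arrs[chrom][pos] = alt
    return {chrom: "".join(arr) for chrom, arr in arrs.items()}


def _sample_fragment_lengths(model: FragmentModel, n: int, read_len: int,
                             rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
    if model.mode < read_len:
        logger.warning("fragment model mode %.1f is below the read length %d",
                       model.mode, read_len)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    n_redrawn = 0
    for _ in range(max_tries):
        need = n - filled
        if need == 0:
            break
        if model.kind == "normal":
            draw = rng.normal(model.location, model.scale, size=need)
        else:
            draw = np.exp(rng.normal(model.location, model.scale, size=need))
        draw = np.rint(draw).astype(np.int64)
        ok = draw >= read_len
        n_ok = int(ok.sum())
        out[filled : filled + n_ok] = draw[ok]
        filled += n_ok
        n_redrawn += need - n_ok
    if filled < n:
        raise ValueError("could not draw enough fragments >= read length")
    if n_redrawn:
        logger.info("redrew %d fragments shorter than the read length", n_redrawn)
    return out


def make_read_pairs(
    haplotypes: list[dict[str, str]],
    genome: GenomeInfo,
    n_pairs: int,
    read_len: int,
    frag_model: FragmentModel,
    profile: Optional[QualityProfile] = None,
    shuffle_fraction: float = 0.0,
    seed: int = 0,
    id_prefix: str = "simread",
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]],
           list[tuple[TruthRecord, TruthRecord]]]:
    """Simulate read pairs: fragments, ends, per-base errors, shuffling.

    Fragments are drawn from ``frag_model`` at uniform genomic positions
    and orientations; each pair reads the two opposite-strand ends of its
    fragment 5'->3'.  Per-base phred scores come from ``profile`` and each
    base is substituted with probability 10^(-Q/10).  A ``shuffle_fraction``
    of second-mate reads is then permuted among themselves, re-assigning
    those pairs; their truth rows are marked disjoint.

    Returns (reads1, reads2, truth_pairs) where reads are (name, sequence,
    quality string) triples ready for FASTQ output.
    """
    if not 0.0 <= shuffle_fraction <= 1.0:
        raise ValueError("shuffle_fraction must be in [0, 1]")
    if profile is None:
        profile = QualityProfile.illumina_like(read_len)
    if profile.read_length != read_len:
        raise ValueError("quality profile length does not match read length")
    rng = np.random.default_rng(seed)

    chroms = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lens / lens.sum()

    frags = _sample_fragment_lengths(frag_model, n_pairs, read_len, rng)
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=chrom_p)
    flip = rng.random(n_pairs) < 0.5  # fragment orientation
    hap_idx = rng.integers(len(haplotypes), size=n_pairs)
    quals1 = profile.sample(n_pairs, rng)
    quals2 = profile.sample(n_pairs, rng)

    reads1: list[tuple[str, str, str]] = []
    reads2: list[tuple[str, str, str]] = []
    truth1: list[TruthRecord] = []
    truth2: list[TruthRecord] = []

    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        L = genome.chrom_lengths[chrom]
        f = int(min(frags[i], L))
        start = int(rng.integers(0, L - f + 1))
        hap = haplotypes[hap_idx[i]][chrom]
        frag_seq = hap[start : start + f]
        name = f"{id_prefix}{i}"
        if not flip[i]:
            r1_seq, r1 = frag_seq[:read_len], ("+", start, start + read_len)
            r2_seq, r2 = revcomp(frag_seq[-read_len:]), ("-", start + f - read_len, start + f)
        else:
            r1_seq, r1 = revcomp(frag_seq[-read_len:]), ("-", start + f - read_len, start + f)
            r2_seq, r2 = frag_seq[:read_len], ("+", start, start + read_len)
        r1_seq = _apply_errors(r1_seq, quals1[i], rng)
        r2_seq = _apply_errors(r2_seq, quals2[i], rng)
        reads1.append((f"{name}/1", r1_seq, _qual_string(quals1[i])))
        reads2.append((f"{name}/2", r2_seq, _qual_string(quals2[i])))
        truth1.append(TruthRecord(name, MATE_FIRST, chrom, r1[0], r1[1], r1[2], True, f))
        truth2.append(TruthRecord(name, MATE_SECOND, chrom, r2[0], r2[1], r2[2], True, f))

    if shuffle_fraction > 0.0:
        k = int(round(shuffle_fraction * n_pairs))
        slots = rng.choice(n_pairs, size=k, replace=False)
        perm = rng.permutation(k)
        new_reads2 = list(reads2)
        new_truth2 = list(truth2)
        for dst, src in zip(slots, slots[perm]):
            name = f"{id_prefix}{dst}"
            _, seq, qual = reads2[src]
            new_reads2[dst] = (f"{name}/2", seq, qual)
            t = truth2[src]
            new_truth2[dst] = TruthRecord(name, MATE_SECOND, t.chrom, t.strand,
                                          t.start, t.end, False, t.fragment_length)
            truth1[dst] = TruthRecord(name, MATE_FIRST, truth1[dst].chrom,
                                      truth1[dst].strand, truth1[dst].start,
                                      truth1[dst].end, False,
                                      truth1[dst].fragment_length)
        reads2, truth2 = new_reads2, new_truth2

    return reads1, reads2, list(zip(truth1, truth2))


def _apply_errors(seq: str, quals: np.ndarray, rng: np.random.Generator) -> str:
    err_p = np.power(10.0, -quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < err_p)[0]
    if hits.size == 0:
        return seq
    arr = list(seq)
    for i in hits:
        arr[i] = _OTHER[arr[i]][rng.integers(3)]
    return "".join(arr)


def _qual_string(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


# ---------------------------------------------------------------------------
# candidate sets

def make_candidate_sets(
    truth_pairs: Sequence[tuple[TruthRecord, TruthRecord]],
    genome: GenomeInfo,
    scoring: ScoringModel,
    read_len: int,
    decoy_rate: float = 1.0,
    cutoff_e: Optional[int] = None,
    suppress_prob: float | tuple[float, float] = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[CandidateSet, CandidateSet]], float, int]:
    """Candidate alignment sets for simulated reads, with known T and e.

    For each read the true-location alignment is emitted with an integer
    score drawn from the tilted (signal) score distribution, truncated at
    the cutoff ``e``, plus Poisson(``decoy_rate``) decoys at uniform
    positions with scores from the noise distribution truncated at ``e``.
    ``suppress_prob`` (scalar, or one value per mate) omits the true
    alignment with that probability, exercising the cutoff-correction and
    empty-mate paths downstream.  All emitted scores are >= e.

    Returns (pairs, T, e).
    """
    rng = np.random.default_rng(seed)
    if isinstance(suppress_prob, (int, float)):
        suppress = (float(suppress_prob), float(suppress_prob))
    else:
        suppress = (float(suppress_prob[0]), float(suppress_prob[1]))

    sd = scoring.score_sd
    mu_signal = scoring.expected_score(read_len)
    mu_noise = mu_signal - sd * sd / scoring.T  # exponential-tilt relation
    if cutoff_e is None:
        cutoff_e = int(round(mu_signal - 2.5 * sd))

    sig_support, sig_p = _discrete_gaussian(mu_signal, sd, lower=cutoff_e)
    noise_support, noise_p = _discrete_gaussian(mu_noise, sd, lower=cutoff_e)

    chroms = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lens / lens.sum()

    def decoys(read_id: str, mate: str) -> list[CandidateAlignment]:
        k = rng.poisson(decoy_rate)
        out = []
        for _ in range(k):
            ci = rng.choice(len(chroms), p=chrom_p)
            chrom = chroms[ci]
            L = genome.chrom_lengths[chrom]
            start = int(rng.integers(0, max(L - read_len, 0) + 1))
            out.append(CandidateAlignment(
                read_id=read_id, mate=mate, chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                ref_start=start, ref_end=start + read_len,
                score=int(rng.choice(noise_support, p=noise_p)),
                read_span=(0, read_len), read_length=read_len,
            ))
        return out

    pairs: list[tuple[CandidateSet, CandidateSet]] = []
    for t1, t2 in truth_pairs:
        sets = []
        for t, sup in ((t1, suppress[0]), (t2, suppress[1])):
            alns = []
            if rng.random() >= sup:
                alns.append(CandidateAlignment(
                    read_id=t.read_id, mate=t.mate, chrom=t.chrom,
                    strand=t.strand, ref_start=t.start, ref_end=t.end,
                    score=int(rng.choice(sig_support, p=sig_p)),
                    read_span=(0, read_len), read_length=read_len,
                ))
            alns.extend(decoys(t.read_id, t.mate))
            sets.append(CandidateSet(t.read_id, t.mate, alns))
        pairs.append((sets[0], sets[1]))
    return pairs, scoring.T, cutoff_e
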