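"""Fragment-length distribution estimation.

The fragment length implied by a pair of opposite-strand alignments is a
signed integer (no bound is imposed).  The distribution is fitted robustly:
location = sample median, scale = interquartile range / 1.34898, the IQR of
a unit normal.  Quantiles use linear interpolation (type 7).  For RNA data
(intron-spanning fragments) the same robust fit is applied to the natural
logs of the lengths, giving a log-normal model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy import stats

from .types import CandidateSet, GenomeInfo

logger = logging.getLogger(__name__)

#: IQR of the standard normal distribution.
NORMAL_IQR = 1.34898


class EstimationError(ValueError):
    """Raised when the fragment-length distribution cannot be estimated."""


@dataclass(frozen=True)
class FragmentModel:
    """Fitted fragment-length distribution pi(f).

    kind     : "normal" (DNA) or "lognormal" (RNA genomic spans).
    location : mean, in bases (normal) or mean of log-lengths (lognormal).
    scale    : standard deviation on the same axis as ``location``.
    n_samples: number of fragment lengths the fit used.

    ``density`` evaluates the continuous density at (integer) fragment
    lengths, a per-base probability-mass approximation; ``density_max`` is
    the closed-form density at the mode (the model's pi_max).
    """

    kind: str
    location: float
    scale: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError(f"scale must be >= 0, got {self.scale}")

    def density(self, f):
        """pi(f) for scalar or array fragment length f (0 outside support)."""
        if self.kind == "normal":
            return stats.norm.pdf(f, loc=self.location, scale=self.scale)
        arr = np.atleast_1d(np.asarray(f, dtype=float))
        out = np.zeros_like(arr)
        pos = arr > 0
        out[pos] = stats.lognorm.pdf(
            arr[pos], s=self.scale, scale=math.exp(self.location)
        )
        if np.isscalar(f) or np.ndim(f) == 0:
            return float(out[0])
        return out

    @property
    def density_max(self) -> float:
        """pi_max: the density at the mode, in closed form."""
        if self.kind == "normal":
            return 1.0 / (self.scale * math.sqrt(2.0 * math.pi))
        # log-normal mode at exp(mu - sigma^2)
        return math.exp(self.scale**2 / 2.0 - self.location) / (
            self.scale * math.sqrt(2.0 * math.pi)
        )

    @property
    def mode(self) -> float:
        if self.kind == "normal":
            return self.location
        return math.exp(self.location - self.scale**2)

    def header_lines(self) -> list[str]:
        """The model as a key=value comment block for output files."""
        return [
            f"# fraglen: kind={self.kind} location={self.location!r} "
            f"scale={self.scale!r} n_samples={self.n_samples}"
        ]

    @classmethod
    def from_header_line(cls, line: str) -> "FragmentModel":
        fields = dict(
            kv.split("=", 1) for kv in line.split(":", 1)[1].split() if "=" in kv
        )
        return cls(
            kind=fields["kind"],
            location=float(fields["location"]),
            scale=float(fields["scale"]),
            n_samples=int(fields.get("n_samples", 0)),
        )


def conjoint_fragment_length(a, b, genome: Optional[GenomeInfo],
                             model: Optional[FragmentModel] = None):
    """Signed fragment length implied by candidates a and b, or None.

    Returns None ("incompatible") unless the two alignments are on the same
    chromosome and on opposite strands.  Otherwise f runs from the forward
    strand member's start to the reverse-strand member's (exclusive) end,
    both in forward reference coordinates; f may be negative or arbitrarily
    large.  On a circular chromosome of length L the member of
    {f, f-L, f+L} with the highest pi is returned (highest conjoint prior);
    without a fitted model the smallest in absolute value is used.  A None
    genome means "all chromosomes linear, lengths unknown".
    """
    if a.chrom != b.chrom:
        return None
    if a.strand == b.strand:
        return None
    fwd, rev = (a, b) if a.strand == "+" else (b, a)
    f = rev.ref_end - fwd.ref_start
    if genome is None:
        return f
    L = genome.length(a.chrom)  # raises for unknown chromosomes
    if not genome.is_circular(a.chrom):
        return f
    wraps = (f, f - L, f + L)
    if model is None:
        return min(wraps, key=abs)
    return max(wraps, key=lambda x: (model.density(x), -abs(x)))


def collect_fragment_lengths(
    pairs: Iterable[tuple[CandidateSet, CandidateSet]],
    genome: GenomeInfo,
    model: Optional[FragmentModel] = None,
) -> list[int]:
    """Record one fragment length per read pair with an unambiguous length.

    For each pair every opposite-strand same-chromosome combination of
    candidates is enumerated; a pair contributes its fragment length only
    when all such combinations agree on exactly one distinct value
    (compared as exact integers).  No bound is applied to the values.
    """
    lengths: list[int] = []
    for A, B in pairs:
        distinct: set[int] = set()
        for a in A:
            for b in B:
                f = conjoint_fragment_length(a, b, genome, model)
                if f is not None:
                    distinct.add(f)
                    if len(distinct) > 1:
                        break
            if len(distinct) > 1:
                break
        if len(distinct) == 1:
            lengths.append(distinct.pop())
    return lengths


def robust_normal_fit(lengths: Sequence[float]) -> FragmentModel:
    """Normal model: mean = median, sd = IQR / 1.34898 (type-7 quantiles)."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 2:
        raise EstimationError(
            "need at least 2 fragment lengths to estimate the distribution; "
            "supply the model manually (kind/location/scale)"
        )
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])  # linear interpolation
    scale = (q3 - q1) / NORMAL_IQR
    if scale == 0.0:
        logger.warning("zero interquartile range; flooring scale at 1.0")
        scale = 1.0
    return FragmentModel("normal", float(med), float(scale), n_samples=arr.size)


def robust_lognormal_fit(lengths: Sequence[float]) -> FragmentModel:
    """Log-normal model: robust normal fit of the log-lengths.

    Non-positive lengths cannot arise from an intron-spanning fragment and
    are discarded (with a log message).
    """
    arr = np.asarray(lengths, dtype=float)
    pos = arr[arr > 0]
    n_dropped = arr.size - pos.size
    if n_dropped:
        logger.info("discarded %d non-positive lengths for log-normal fit", n_dropped)
    if pos.size < 2:
        raise EstimationError(
            "need at least 2 positive fragment lengths for the log-normal fit"
        )
    base = robust_normal_fit(np.log(pos))
    return FragmentModel("lognormal", base.location, base.scale, n_samples=pos.size)


def fit(lengths: Sequence[float], kind: str = "normal") -> FragmentModel:
    if kind == "normal":
        return robust_normal_fit(lengths)
    if kind == "lognormal":
        return robust_lognormal_fit(lengths)
    raise ValueError(f"unknown model kind {kind!r}")


def reservoir_sample(stream: Iterable, k: int, rng: np.random.Generator) -> list:
    """Uniform sample of k items from a stream of unknown length."""
    sample: list = []
    for i, item in enumerate(stream):
        if i < k:
            sample.append(item)
        else:
            j = rng.integers(0, i + 1)
            if j < k:
                sample[j] = item
    return sample


def estimate_from_sample(
    pairs: Iterable[tuple[CandidateSet, CandidateSet]],
    genome: GenomeInfo,
    sample_size: int,
    seed: int,
    kind: str = "normal",
) -> FragmentModel:
    """Fit the fragment model from a reservoir sample of read pairs.

    Deterministic for a fixed seed; identical to the full-stream fit when
    ``sample_size`` is at least the number of pairs.
    """
    if sample_size < 2:
        raise EstimationError("sample_size must be >= 2")
    rng = np.random.default_rng(seed)
    sampled = reservoir_sample(pairs, sample_size, rng)
    lengths = collect_fragment_lengths(sampled, genome)
    if len(lengths) < 2:
        raise EstimationError(
            f"only {len(lengths)} usable fragment lengths in the sample; "
            "increase the sample size or supply the model manually"
        )
    return fit(lengths, kind)


def estimate_disjoint_prior(
    pairs: Iterable[tuple[CandidateSet, CandidateSet]],
    model: FragmentModel,
    genome: GenomeInfo,
    tail_ratio: float = 1e-6,
    floor: float = 1e-4,
    default: float = 0.01,
) -> float:
    """Estimate d from uniquely mapping read pairs.

    Among pairs where both ends have exactly one candidate, d is the
    fraction whose unique combination is incompatible (different chromosome
    or same strand) or falls in the far tail of the fitted distribution
    (density below ``tail_ratio * pi_max``).  Returns ``default`` with a
    warning when no uniquely mapping pairs exist; the estimate is floored
    at ``floor``.
    """
    n_unique = 0
    n_disjoint = 0
    threshold = tail_ratio * model.density_max
    for A, B in pairs:
        if len(A) != 1 or len(B) != 1:
            continue
        n_unique += 1
        f = conjoint_fragment_length(A.alignments[0], B.alignments[0], genome, model)
        if f is None or model.density(f) < threshold:
            n_disjoint += 1
    if n_unique == 0:
        logger.warning(
            "no uniquely mapping pairs; falling back to default d=%g", default
        )
        return default
    return max(n_disjoint / n_unique, floor)
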