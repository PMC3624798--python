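"""Core domain types shared across the package.

Coordinates are 0-based, half-open, on the forward strand of the reference
throughout; strand-relative conventions of external formats (MAF) are
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


MATE_FIRST = "first"
MATE_SECOND = "second"


@dataclass(frozen=True)
class CandidateAlignment:
    """One scored local alignment of one read end to the reference.

    ``score`` is an integer in the aligner's score units; it is interpreted
    as ``T * ln(likelihood ratio)`` where ``T`` is the scoring scheme's scale
    factor.  ``read_span`` is (qstart, qend), 0-based half-open on the
    forward orientation of the read.
    """

    read_id: str
    mate: str  # "first" | "second"
    chrom: str
    strand: str  # "+" | "-"
    ref_start: int
    ref_end: int
    score: int
    read_span: tuple[int, int] = (0, 0)
    read_length: int = 0  # 0 = unknown
    read_seq: str = ""  # optional, carried through for SAM output

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"ref_start must be < ref_end ({self.ref_start} >= {self.ref_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mate not in (MATE_FIRST, MATE_SECOND):
            raise ValueError(f"mate must be 'first' or 'second', got {self.mate!r}")
        qs, qe = self.read_span
        if qs > qe:
            raise ValueError(f"read_span start must be <= end, got {self.read_span}")


@dataclass
class CandidateSet:
    """All candidate alignments of one read end (possibly empty)."""

    read_id: str
    mate: str
    alignments: list[CandidateAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for aln in self.alignments:
            if aln.read_id != self.read_id or aln.mate != self.mate:
                raise ValueError(
                    f"alignment {aln.read_id}/{aln.mate} does not belong to "
                    f"candidate set {self.read_id}/{self.mate}"
                )

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)

    @property
    def is_empty(self) -> bool:
        return not self.alignments


@dataclass(frozen=True)
class PairParams:
    """Constants of the pairing model.

    d : prior probability that the two reads of a pair come from disjoint
        genomic locations.
    T : score scale factor (score units per nat); a property of the scoring
        scheme, it has no default and must come from the aligner run.
    e : integer score cutoff used when generating candidates; alignments
        scoring below e are unobserved.
    two_g : number of bases in both strands of the haploid genome (2g).
    apply_cutoff_correction : include the sub-threshold "unlucky case" mass.
    """

    d: float
    T: float
    e: int
    two_g: int
    apply_cutoff_correction: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"d must be in [0, 1], got {self.d}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.two_g < 1:
            raise ValueError(f"two_g must be >= 1, got {self.two_g}")


@dataclass
class GenomeInfo:
    """Chromosome lengths and circularity flags."""

    chrom_lengths: dict[str, int]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has length {length} < 1")

    def is_circular(self, chrom: str) -> bool:
        return self.circular.get(chrom, False)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not present in genome table") from None

    @property
    def two_g(self) -> int:
        """Bases in both strands: 2 * sum of chromosome lengths."""
        return 2 * sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class PosteriorRecord:
    """A candidate alignment annotated with its pairing posterior.

    ``mismap = 1 - posterior`` is the probability that this alignment does
    not represent the read's true genomic source; ``mapq`` is its phred
    scaled integer encoding.  ``alignment`` is None for an explicit
    "unmapped" record (both candidate sets empty).
    """

    read_id: str
    mate: str
    alignment: Optional[CandidateAlignment]
    posterior: float
    mismap: float
    mapq: int

    @property
    def is_unmapped(self) -> bool:
        return self.alignment is None
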