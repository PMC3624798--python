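"""Readers and writers for the alignment and result formats.

Supported formats:

* MAF blocks as emitted by local aligners: an ``a`` line with key=value
  fields (``score=`` required), then the reference ``s`` line, then the
  read ``s`` line.  MAF uses strand-relative coordinates: a ``-`` strand
  s-line counts from the start of the reverse-complemented sequence.
  Internally everything is 0-based half-open on the forward strand; the
  conversion happens only here.
* A 12-column tab dialect (score, ref name/start/alnSize/strand/seqSize,
  read name/start/alnSize/strand/seqSize, gapless block string), smaller
  and faster to parse than MAF.
* SAM 1.x for annotated output (text only, no BAM).
* FASTA / FASTQ (Sanger phred+33) via Biopython.

The score scale T and the score cutoff e are properties of the alignment
run and travel in comment headers (``# T=...``, ``# e=...``); a fitted
fragment model travels the same way (``# fraglen: ...``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO

from .fraglen import FragmentModel
from .types import (
    MATE_FIRST,
    MATE_SECOND,
    CandidateAlignment,
    CandidateSet,
    GenomeInfo,
    PosteriorRecord,
)

PathOrHandle = Union[str, TextIO]

_MATE_SUFFIX = {"1": MATE_FIRST, "2": MATE_SECOND}
_SUFFIX_OF = {MATE_FIRST: "1", MATE_SECOND: "2"}


def _open(path_or_handle: PathOrHandle, mode: str = "r") -> tuple[TextIO, bool]:
    if isinstance(path_or_handle, (str, bytes)):
        return open(path_or_handle, mode), True
    return path_or_handle, False


# ---------------------------------------------------------------------------
# strand-relative <-> forward coordinates (MAF s-line convention)

def maf_to_forward(start: int, aln_size: int, strand: str, seq_size: int) -> tuple[int, int]:
    """Convert a MAF s-line interval to forward-strand 0-based half-open."""
    if strand == "+":
        return start, start + aln_size
    return seq_size - (start + aln_size), seq_size - start


def forward_to_maf(fwd_start: int, fwd_end: int, strand: str, seq_size: int) -> tuple[int, int]:
    """Inverse of :func:`maf_to_forward`; returns (start, aln_size)."""
    if strand == "+":
        return fwd_start, fwd_end - fwd_start
    return seq_size - fwd_end, fwd_end - fwd_start


# ---------------------------------------------------------------------------
# headers

def format_params_header(T: float, e: int, model: Optional[FragmentModel] = None) -> list[str]:
    lines = [f"# T={T!r}", f"# e={e}"]
    if model is not None:
        lines.extend(model.header_lines())
    return lines


def parse_header_line(line: str, header: dict) -> bool:
    """Parse one comment line into ``header``; True if it was a comment."""
    if not line.startswith("#"):
        return False
    body = line[1:].strip()
    if body.startswith("fraglen:"):
        header["fraglen"] = FragmentModel.from_header_line(body)
        return True
    for kv in body.split():
        if "=" not in kv:
            continue
        key, val = kv.split("=", 1)
        if key == "T":
            header["T"] = float(val)
        elif key == "e":
            header["e"] = int(val)
    return True


# ---------------------------------------------------------------------------
# MAF

@dataclass
class SLine:
    name: str
    start: int
    aln_size: int
    strand: str
    seq_size: int
    text: str  # aligned sequence, possibly gapped


@dataclass
class MafBlock:
    """One pairwise MAF alignment block (reference line, then read line)."""

    score: int
    ref: SLine
    read: SLine
    extras: dict = field(default_factory=dict)  # e.g. mismap=...

    def to_lines(self) -> list[str]:
        a = f"a score={self.score}"
        for key, val in self.extras.items():
            a += f" {key}={val}"
        out = [a]
        for s in (self.ref, self.read):
            out.append(
                f"s {s.name} {s.start} {s.aln_size} {s.strand} {s.seq_size} {s.text}"
            )
        out.append("")
        return out


def read_maf_blocks(handle: TextIO, header: Optional[dict] = None) -> Iterator[MafBlock]:
    score = None
    extras: dict = {}
    slines: list[SLine] = []
    for lineno, raw in enumerate(handle, 1):
        line = raw.rstrip("\n")
        if header is not None and line.startswith("#"):
            parse_header_line(line, header)
            continue
        if not line.strip():
            if slines:
                yield _finish_block(score, extras, slines, lineno)
                score, extras, slines = None, {}, []
            continue
        fields = line.split()
        if fields[0] == "a":
            if slines:
                yield _finish_block(score, extras, slines, lineno)
                slines = []
            extras = {}
            score = None
            for kv in fields[1:]:
                key, _, val = kv.partition("=")
                if key == "score":
                    score = int(val)
                else:
                    extras[key] = val
            if score is None:
                raise ValueError(f"line {lineno}: 'a' line without score=")
        elif fields[0] == "s":
            if len(fields) != 7:
                raise ValueError(f"line {lineno}: malformed s line: {line!r}")
            slines.append(
                SLine(fields[1], int(fields[2]), int(fields[3]), fields[4],
                      int(fields[5]), fields[6])
            )
        # other MAF line types (q, p, i) are ignored
    if slines:
        yield _finish_block(score, extras, slines, lineno)


def _finish_block(score, extras, slines, lineno) -> MafBlock:
    if score is None or len(slines) != 2:
        raise ValueError(f"near line {lineno}: incomplete MAF block")
    return MafBlock(score=score, ref=slines[0], read=slines[1], extras=extras)


def maf_block_to_candidate(block: MafBlock, mate: str, read_id: str) -> CandidateAlignment:
    ref_start, ref_end = maf_to_forward(
        block.ref.start, block.ref.aln_size, block.ref.strand, block.ref.seq_size
    )
    qstart, qend = maf_to_forward(
        block.read.start, block.read.aln_size, block.read.strand, block.read.seq_size
    )
    # alignment strand of the read relative to the (forward) reference
    strand = "+" if block.ref.strand == block.read.strand else "-"
    return CandidateAlignment(
        read_id=read_id,
        mate=mate,
        chrom=block.ref.name,
        strand=strand,
        ref_start=ref_start,
        ref_end=ref_end,
        score=block.score,
        read_span=(qstart, qend),
        read_length=block.read.seq_size,
    )


def candidate_to_maf_block(aln: CandidateAlignment, genome: GenomeInfo,
                           extras: Optional[dict] = None) -> MafBlock:
    seq_size = genome.length(aln.chrom)
    ref = SLine(aln.chrom, aln.ref_start, aln.ref_end - aln.ref_start, "+",
                seq_size, "*")
    qstart, qend = aln.read_span
    read_len = aln.read_length or qend
    start, size = forward_to_maf(qstart, qend, aln.strand, read_len)
    read = SLine(f"{aln.read_id}/{_SUFFIX_OF[aln.mate]}", start, size,
                 aln.strand, read_len, "*")
    return MafBlock(score=aln.score, ref=ref, read=read, extras=dict(extras or {}))


# ---------------------------------------------------------------------------
# 12-column tab dialect

def tab_line(aln: CandidateAlignment, genome: GenomeInfo, mismap: Optional[float] = None) -> str:
    qstart, qend = aln.read_span
    read_len = aln.read_length or qend
    rstart, rsize = forward_to_maf(qstart, qend, aln.strand, read_len)
    cols = [
        str(aln.score),
        aln.chrom,
        str(aln.ref_start),
        str(aln.ref_end - aln.ref_start),
        "+",
        str(genome.length(aln.chrom)),
        f"{aln.read_id}/{_SUFFIX_OF[aln.mate]}",
        str(rstart),
        str(rsize),
        aln.strand,
        str(read_len),
        str(rsize),  # single gapless block
    ]
    line = "\t".join(cols)
    if mismap is not None:
        line += f"\tmismap={mismap:.2e}"
    return line


def parse_tab_line(line: str, lineno: int) -> tuple[str, CandidateAlignment]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: expected 12 tab-separated columns")
    try:
        score = int(fields[0])
        chrom = fields[1]
        ref_start = int(fields[2])
        ref_aln = int(fields[3])
        ref_strand = fields[4]
        name = fields[6]
        rstart = int(fields[7])
        rsize = int(fields[8])
        rstrand = fields[9]
        rseq_size = int(fields[10])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable field: {exc}") from None
    strand = "+" if ref_strand == rstrand else "-"
    qstart, qend = maf_to_forward(rstart, rsize, rstrand, rseq_size)
    base_id, mate = split_mate_suffix(name)
    aln = CandidateAlignment(
        read_id=base_id,
        mate=mate,
        chrom=chrom,
        strand=strand,
        ref_start=ref_start,
        ref_end=ref_start + ref_aln,
        score=score,
        read_span=(qstart, qend),
        read_length=rseq_size,
    )
    return name, aln


def split_mate_suffix(name: str) -> tuple[str, str]:
    m = re.fullmatch(r"(.*)/([12])", name)
    if not m:
        raise ValueError(
            f"read {name!r}: cannot determine mate (expected /1 or /2 suffix)"
        )
    return m.group(1), _MATE_SUFFIX[m.group(2)]


# ---------------------------------------------------------------------------
# grouped candidate reading

def read_candidates(
    path_or_handle: PathOrHandle,
    fmt: str = "tab",
    header: Optional[dict] = None,
) -> Iterator[tuple[CandidateSet, CandidateSet]]:
    """Stream (A, B) candidate-set pairs grouped by read pair.

    The input must be groupable by read name (all records of one pair
    adjacent).  Mates are identified by the /1 and /2 name suffixes.  If a
    dict is passed as ``header``, comment-header values (T, e, fragment
    model) are stored into it as they are encountered.  Memory use is one
    read pair, never the whole file.
    """
    handle, owned = _open(path_or_handle)
    if header is None:
        header = {}
    try:
        if fmt == "tab":
            yield from _group_pairs(_iter_tab(handle, header))
        elif fmt == "maf":
            yield from _group_pairs(_iter_maf(handle, header))
        else:
            raise ValueError(f"unknown candidate format {fmt!r}")
    finally:
        if owned:
            handle.close()


def _iter_tab(handle: TextIO, header: dict) -> Iterator[CandidateAlignment]:
    for lineno, line in enumerate(handle, 1):
        if parse_header_line(line, header):
            continue
        if not line.strip():
            continue
        _, aln = parse_tab_line(line, lineno)
        yield aln


def _iter_maf(handle: TextIO, header: dict) -> Iterator[CandidateAlignment]:
    for block in read_maf_blocks(handle, header):
        base_id, mate = split_mate_suffix(block.read.name)
        yield maf_block_to_candidate(block, mate, base_id)


def _group_pairs(
    alns: Iterable[CandidateAlignment],
) -> Iterator[tuple[CandidateSet, CandidateSet]]:
    current_id: Optional[str] = None
    first: list[CandidateAlignment] = []
    second: list[CandidateAlignment] = []

    def flush():
        return (
            CandidateSet(current_id, MATE_FIRST, first),
            CandidateSet(current_id, MATE_SECOND, second),
        )

    for aln in alns:
        if aln.read_id != current_id:
            if current_id is not None:
                yield flush()
            current_id, first, second = aln.read_id, [], []
        (first if aln.mate == MATE_FIRST else second).append(aln)
    if current_id is not None:
        yield flush()


def write_candidates(
    pairs: Iterable[tuple[CandidateSet, CandidateSet]],
    path_or_handle: PathOrHandle,
    genome: GenomeInfo,
    T: float,
    e: int,
    fmt: str = "tab",
    model: Optional[FragmentModel] = None,
) -> None:
    handle, owned = _open(path_or_handle, "w")
    try:
        for line in format_params_header(T, e, model):
            handle.write(line + "\n")
        for A, B in pairs:
            for S in (A, B):
                for aln in S:
                    if fmt == "tab":
                        handle.write(tab_line(aln, genome) + "\n")
                    else:
                        for line in candidate_to_maf_block(aln, genome).to_lines():
                            handle.write(line + "\n")
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# annotated output

def write_annotated(
    record_pairs: Iterable[tuple[list[PosteriorRecord], list[PosteriorRecord]]],
    path_or_handle: PathOrHandle,
    genome: GenomeInfo,
    fmt: str = "tab",
    mismap_filter: Optional[float] = None,
    header_lines: Iterable[str] = (),
) -> None:
    """Write posterior-annotated alignments as tab, MAF, or SAM.

    Tab and MAF outputs carry ``mismap=`` with the raw probability in
    scientific notation (3 significant digits); SAM encodes the mismap as
    MAPQ plus an ``mp:f`` tag.  ``mismap_filter`` drops records with a
    larger mismap; a filter at 0.5 keeps at most one record per read.
    """
    handle, owned = _open(path_or_handle, "w")
    try:
        if fmt == "sam":
            _write_sam_header(handle, genome)
        else:
            for line in header_lines:
                handle.write(line + "\n")
        for rec_a, rec_b in record_pairs:
            rec_a = _filtered(rec_a, mismap_filter)
            rec_b = _filtered(rec_b, mismap_filter)
            if fmt == "sam":
                _write_sam_pair(handle, rec_a, rec_b, genome)
            else:
                for rec in rec_a + rec_b:
                    if rec.is_unmapped:
                        continue
                    if fmt == "tab":
                        handle.write(tab_line(rec.alignment, genome, rec.mismap) + "\n")
                    else:
                        block = candidate_to_maf_block(
                            rec.alignment, genome, {"mismap": f"{rec.mismap:.2e}"}
                        )
                        for line in block.to_lines():
                            handle.write(line + "\n")
    finally:
        if owned:
            handle.close()


def _filtered(recs: list[PosteriorRecord], mismap_filter: Optional[float]):
    if mismap_filter is None:
        return recs
    return [r for r in recs if r.is_unmapped or r.mismap <= mismap_filter]


def _write_sam_header(handle: TextIO, genome: GenomeInfo) -> None:
    handle.write("@HD\tVN:1.6\tSO:unsorted\n")
    for name, length in genome.chrom_lengths.items():
        handle.write(f"@SQ\tSN:{name}\tLN:{length}\n")
    handle.write("@PG\tID:pairprob\tPN:pairprob\n")


def _best(recs: list[PosteriorRecord]) -> Optional[PosteriorRecord]:
    mapped = [r for r in recs if not r.is_unmapped]
    if not mapped:
        return None
    return min(mapped, key=lambda r: r.mismap)


def _cigar(aln: CandidateAlignment) -> str:
    qstart, qend = aln.read_span
    read_len = aln.read_length or qend
    parts = []
    if qstart:
        parts.append(f"{qstart}S")
    parts.append(f"{qend - qstart}M")
    if read_len - qend:
        parts.append(f"{read_len - qend}S")
    return "".join(parts)


def _write_sam_pair(handle: TextIO, rec_a, rec_b, genome: GenomeInfo) -> None:
    for own, other, mate_flag in ((rec_a, rec_b, 0x40), (rec_b, rec_a, 0x80)):
        mate_best = _best(other)
        for rec in own:
            flag = 0x1 | mate_flag
            if rec.is_unmapped:
                flag |= 0x4
                if mate_best is None:
                    flag |= 0x8
                handle.write(
                    f"{rec.read_id}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
                )
                continue
            aln = rec.alignment
            genome.length(aln.chrom)  # unknown chromosome -> KeyError
            if aln.strand == "-":
                flag |= 0x10
            if mate_best is None:
                flag |= 0x8
                rnext, pnext = "*", 0
            else:
                m = mate_best.alignment
                if m.strand == "-":
                    flag |= 0x20
                rnext = "=" if m.chrom == aln.chrom else m.chrom
                pnext = m.ref_start + 1
            seq = aln.read_seq or "*"
            handle.write(
                f"{rec.read_id}\t{flag}\t{aln.chrom}\t{aln.ref_start + 1}\t"
                f"{rec.mapq}\t{_cigar(aln)}\t{rnext}\t{pnext}\t0\t{seq}\t*\t"
                f"mp:f:{rec.mismap:.6g}\n"
            )


def read_annotated(
    path_or_handle: PathOrHandle,
    fmt: str = "tab",
    mapq_cap: int = 60,
) -> Iterator[PosteriorRecord]:
    """Read back mismap-annotated tab or MAF output as PosteriorRecords."""
    from .model import mismap_to_mapq  # local import to avoid a cycle

    handle, owned = _open(path_or_handle)
    try:
        if fmt == "tab":
            for lineno, line in enumerate(handle, 1):
                if line.startswith("#") or not line.strip():
                    continue
                _, aln = parse_tab_line(line, lineno)
                fields = line.rstrip("\n").split("\t")
                mismap = None
                for extra in fields[12:]:
                    if extra.startswith("mismap="):
                        mismap = float(extra.split("=", 1)[1])
                if mismap is None:
                    raise ValueError(f"line {lineno}: no mismap= annotation")
                yield PosteriorRecord(aln.read_id, aln.mate, aln, 1.0 - mismap,
                                      mismap, mismap_to_mapq(mismap, mapq_cap))
        elif fmt == "maf":
            for block in read_maf_blocks(handle, header={}):
                if "mismap" not in block.extras:
                    raise ValueError(f"MAF block for {block.read.name}: no mismap=")
                base_id, mate = split_mate_suffix(block.read.name)
                aln = maf_block_to_candidate(block, mate, base_id)
                mismap = float(block.extras["mismap"])
                yield PosteriorRecord(base_id, mate, aln, 1.0 - mismap, mismap,
                                      mismap_to_mapq(mismap, mapq_cap))
        else:
            raise ValueError(f"cannot read annotated format {fmt!r}")
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA / FASTQ / tables

def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str) -> None:
    """Write (name, sequence, quality-string) records as Sanger FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((rec.id, str(rec.seq), "".join(chr(q + 33) for q in quals)))
    return out


def genome_info_from_fasta(path: str, circular: Iterable[str] = ()) -> GenomeInfo:
    circ = set(circular)
    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    return GenomeInfo(lengths, {name: name in circ for name in lengths})


def write_genome_table(genome: GenomeInfo, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chrom_lengths.items():
            flag = "circular" if genome.is_circular(name) else "linear"
            fh.write(f"{name}\t{length}\t{flag}\n")


def read_genome_table(path: str) -> GenomeInfo:
    lengths: dict[str, int] = {}
    circ: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 'name length [circular]'")
            lengths[fields[0]] = int(fields[1])
            circ[fields[0]] = len(fields) > 2 and fields[2] == "circular"
    return GenomeInfo(lengths, circ)
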