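"""Benchmark evaluation: accuracy/error curves and posterior calibration.

A prediction is "correct" when it names the read's true chromosome and
strand and its reference interval overlaps the truth interval by at least
``min_overlap`` bases (configurable).  Curves are swept over mismap
thresholds, never loosening beyond mismap 0.5: above 0.5 a read can carry
more than one qualifying alignment, which would complicate counting
secondary mappings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .fraglen import FragmentModel
from .model import pair_posteriors
from .simulate import TruthRecord
from .types import CandidateSet, GenomeInfo, PairParams, PosteriorRecord


def run_pairing(
    candidate_pairs: Iterable[tuple[CandidateSet, CandidateSet]],
    params: PairParams,
    model: FragmentModel,
    genome: GenomeInfo,
) -> list[tuple[list[PosteriorRecord], list[PosteriorRecord]]]:
    """Posterior records for every candidate pair (convenience driver)."""
    return [pair_posteriors(A, B, params, model, genome)
            for A, B in candidate_pairs]


def is_correct(rec: PosteriorRecord, truth: TruthRecord, min_overlap: int = 1) -> bool:
    aln = rec.alignment
    if aln is None:
        return False
    if aln.chrom != truth.chrom or aln.strand != truth.strand:
        return False
    overlap = min(aln.ref_end, truth.end) - max(aln.ref_start, truth.start)
    return overlap >= min_overlap


def _truth_index(truth: Iterable[TruthRecord]) -> dict[tuple[str, str], TruthRecord]:
    return {(t.read_id, t.mate): t for t in truth}


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    frac_correct: float
    frac_wrong: float


def evaluate(
    records: Iterable[PosteriorRecord],
    truth: Sequence[TruthRecord],
    min_overlap: int = 1,
    max_mismap: float = 0.5,
) -> list[CurvePoint]:
    """Threshold-sweep curve of correctly and wrongly mapped fractions.

    Predictions with mismap above ``max_mismap`` are discarded first; at
    most one prediction per read then remains.  For every distinct
    remaining mismap value t, one point gives the fraction of all reads in
    the truth table mapped correctly/wrongly by predictions with
    mismap <= t.  Both fractions are non-decreasing as t grows.
    """
    index = _truth_index(truth)
    kept: list[tuple[float, bool]] = []
    for rec in records:
        if rec.is_unmapped or rec.mismap > max_mismap:
            continue
        key = (rec.read_id, rec.mate)
        if key not in index:
            raise ValueError(f"prediction for unknown read {rec.read_id}/{rec.mate}")
        kept.append((rec.mismap, is_correct(rec, index[key], min_overlap)))
    n_reads = len(index)
    if n_reads == 0:
        raise ValueError("empty truth table")
    kept.sort(key=lambda x: x[0])
    points: list[CurvePoint] = []
    n_correct = n_wrong = 0
    for i, (mismap, ok) in enumerate(kept):
        if ok:
            n_correct += 1
        else:
            n_wrong += 1
        if i + 1 == len(kept) or kept[i + 1][0] != mismap:
            points.append(CurvePoint(mismap, n_correct / n_reads, n_wrong / n_reads))
    return points


def correct_at_wrong(curve: Sequence[CurvePoint], max_wrong: float) -> float:
    """Largest correctly-mapped fraction achieved at error <= max_wrong."""
    best = 0.0
    for p in curve:
        if p.frac_wrong <= max_wrong:
            best = max(best, p.frac_correct)
    return best


def accuracy_at_threshold(
    records: Iterable[PosteriorRecord],
    truth: Sequence[TruthRecord],
    max_mismap: float = 0.5,
    min_overlap: int = 1,
    restrict_to: Optional[set[tuple[str, str]]] = None,
) -> tuple[float, float]:
    """(fraction correct, fraction wrong) at one mismap threshold.

    ``restrict_to`` limits both the denominator and the predictions to a
    subset of (read_id, mate) keys, e.g. the conjoint reads of a shuffled
    benchmark.
    """
    index = _truth_index(truth)
    if restrict_to is not None:
        index = {k: v for k, v in index.items() if k in restrict_to}
    n_correct = n_wrong = 0
    for rec in records:
        key = (rec.read_id, rec.mate)
        if key not in index:
            continue
        if rec.is_unmapped or rec.mismap > max_mismap:
            continue
        if is_correct(rec, index[key], min_overlap):
            n_correct += 1
        else:
            n_wrong += 1
    n = len(index)
    return n_correct / n, n_wrong / n


def write_curve(curve: Sequence[CurvePoint], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tfrac_correct\tfrac_wrong\n")
        for p in curve:
            fh.write(f"{p.threshold:.6g}\t{p.frac_correct:.6g}\t{p.frac_wrong:.6g}\n")


@dataclass(frozen=True)
class CalibrationBin:
    mean_mismap: float
    n: int
    n_wrong: int

    @property
    def empirical(self) -> float:
        return self.n_wrong / self.n if self.n else float("nan")


def calibration_bins(
    records: Iterable[PosteriorRecord],
    truth: Sequence[TruthRecord],
    edges: Sequence[float] = (0.0, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.2, 0.35,
                              0.5, 0.65, 0.8, 0.95, 1.0 + 1e-12),
    min_overlap: int = 1,
) -> list[CalibrationBin]:
    """Bin all candidates by predicted mismap against the observed error rate.

    On data generated from the model's own assumptions the empirical error
    fraction in each bin should match the bin's mean predicted mismap.
    """
    index = _truth_index(truth)
    mismaps: list[float] = []
    wrong: list[bool] = []
    for rec in records:
        if rec.is_unmapped:
            continue
        t = index[(rec.read_id, rec.mate)]
        mismaps.append(rec.mismap)
        wrong.append(not is_correct(rec, t, min_overlap))
    m = np.asarray(mismaps)
    w = np.asarray(wrong)
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (m >= lo) & (m < hi)
        n = int(mask.sum())
        if n == 0:
            continue
        bins.append(CalibrationBin(float(m[mask].mean()), n, int(w[mask].sum())))
    return bins
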