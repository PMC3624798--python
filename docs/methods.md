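# Methods

## The pairing model

A paired-end sequencing run reads the two opposite-strand ends of a DNA
fragment.  Given a set `A` of candidate local alignments for read α and a
set `B` for its mate β — produced by any local aligner that reports integer
scores interpretable as scaled log-likelihood ratios — the package computes,
for each candidate `a ∈ A`, the marginal posterior probability that `a` is
the read's true genomic source.  This is a *per-alignment* marginal, not a
per-pair score: the mate's evidence is summed over all of its candidates.

The generative assumptions:

* With prior probability `1 − d` the pair is **conjoint**: it derives from
  one contiguous fragment.  The first end falls uniformly on either strand
  of the genome (probability `1/2g` per position, `2g` = bases in both
  strands of the haploid genome), and the implied fragment length `f`
  follows a fitted density `π(f)`.  Joint prior: `(1 − d) · π(f_ab) / 2g`,
  zero when `a` and `b` are on different chromosomes or the same strand.
* With prior `d` the pair is **disjoint** (translocation, mis-assembly,
  contamination): both ends are placed independently and uniformly, prior
  `d / (2g)²`.
* The likelihood of the read data given a placement is proportional to
  `exp(s_a/T) · exp(s_b/T)`, where `s` is the alignment score and `T` the
  scoring scheme's scale factor (score units per nat).  `T` is a property
  of the aligner's substitution/gap scores and is never guessed: it must
  arrive in the input header or a flag.

Bayes' rule then gives the posterior of `a` as a ratio of sums over
`B × {conjoint, disjoint}`.  Scaling all priors by `(2g)²`, the numerator
factorizes as

    N(a) = exp(s_a/T) · [ (1 − d) · 2g · c(a) + d · Y ]
    c(a) = Σ_{b compatible} exp(s_b/T) · π(f_ab),   Y = Σ_b exp(s_b/T)

so a pair with `m + n` candidates costs `O(m·n)` once, not per candidate.
An explicit double-sum implementation (`brute_force_posteriors`) is kept as
a test oracle and must agree with the factorized path to 1e-12 relative.

The **mismap probability** is `1 − posterior`; its phred encoding
`round(−10·log10(mismap))`, capped at 60 by default, becomes SAM MAPQ.
Because the marginals over one read sum to at most 1, at most one candidate
per read can have mismap below 0.5.

### Fragment-length convention

`f_ab` runs from the forward-strand member's start to the reverse-strand
member's exclusive end, in forward reference coordinates.  It is signed and
unbounded; a wrong-order pair simply lands in the far tail of `π` rather
than being rejected by a hard rule.  On a chromosome flagged circular with
length `L`, the member of `{f, f − L, f + L}` with the highest `π` is used,
which makes posteriors invariant to translating a pair across the origin.
During fragment-length *collection*, before any model exists, the smallest
absolute value of the three is used instead.

### Score cutoff correction

Aligners only report candidates scoring at least a cutoff `e`.  If a read's
true alignment scored `e − 1` (the best possible sub-cutoff integer score)
while a spurious alignment scored `e`, the naive posterior would confidently
pick the spurious one.  The correction adds to the denominator the mass of a
pessimistic hypothetical alignment: score `e − 1`, sitting at the optimal
fragment distance from the mate's best candidate,

    w = exp((e−1)/T) · [ (1 − d) · 2g · π_max · exp(s_B_max/T) + d · Y ]

where `π_max` is the density mode in closed form.  `w` enters only the
denominator of the read whose hypothetical it is; the mate gets the
symmetric term.  The hypothetical carries both a conjoint and a disjoint
component, for consistency with real candidates.  This is a deliberately
conservative device against false positives, not an exact marginal over the
censored score range — with the correction on, reported mismaps near the
`w/Z` scale are upper-bound-flavoured.  Posteriors then sum to `1 − w/Z`
over the read's candidates.

When the mate has **no candidates at all**, the read is scored as if the
mate had a single alignment on a different chromosome from everything in
`A`.  That virtual alignment's score factor multiplies every term in the
ratio and cancels, so it needs no value; without the correction the result
is the within-read score softmax, with it the closed form in
`empty_mate_posteriors`.  A pair with no candidates on either end produces
explicit unmapped records rather than disappearing.

### Numerics

All exponentials are computed as `exp((s − shift)/T)` with `shift` the
maximum relevant score per read (including `e − 1`), so overflow is
impossible and only ratios matter; posteriors are shift-invariant to 1e-12
relative.  Posteriors below ~1e-300 can underflow to subnormals where
relative precision degrades; they are clamped to `[0, 1]` and treated as
zero for all practical purposes.  A degenerate instance with `d = 0`, no
compatible geometry and no correction has zero total mass; every posterior
is reported as 0 rather than dividing by zero.

## Fragment-length estimation

From every read pair whose opposite-strand same-chromosome candidate
combinations imply **exactly one distinct** integer fragment length, that
length is recorded (exact integer comparison, no tolerance, no bound on the
value).  The normal model then takes location = sample median and scale =
IQR / 1.34898 — the IQR of a unit normal — using linear-interpolation
(type-7) quantiles.  This resists gross outliers: 5% contamination at ±1e6
moves the estimates by under 0.07 σ (the closed-form mixture-quantile
shift), where moment estimates would be off by orders of magnitude.  A zero
IQR is floored at scale 1.0 with a warning; fewer than two usable lengths
is an error asking for a manual model.

RNA mode applies the same robust fit to the natural logs of the (positive)
lengths, giving a single log-normal — a deliberate simplification of the
short-intron/long-intron mixture seen in real RNA data, compensated by
raising the default `d` from 0.01 to 0.02.  `π_max` for the log-normal is
the density at the mode `exp(location − scale²)`.

`π(f)` is the continuous density evaluated at integer `f` (per-base mass
approximation; no binning).  Estimation can run on a seeded reservoir
sample of read pairs instead of the full stream; with the sample at least
as large as the stream the result is identical to the full fit.

`d` itself defaults to 0.01 (0.02 in RNA mode).  Behind a flag it can be
estimated as the fraction of uniquely-mapping pairs (one candidate per end)
whose combination is incompatible or has `π(f) < π_max · 1e-6` — the tail
threshold and the floor of 1e-4 are this package's choices; with no unique
pairs the default is returned with a warning.

## What the synthetic generator emulates

`simulate` builds a toy version of a full benchmark: a uniform-random
genome at a chosen GC content (default 0.41, one 1 Mb chromosome); two
haplotypes with independent per-site SNPs; fragments drawn from the
fragment model (re-drawn if shorter than the read length) at uniform
positions and orientations; 100 bp end reads with per-base substitution
errors driven by a position × phred quality profile (default: an
Illumina-like profile degrading from Q38 toward Q30 at the 3' end); and an
optional shuffle of a fraction of second-mate reads among themselves,
which re-assigns those pairs and marks their truth rows disjoint — the toy
analogue of translocation-spanning pairs.

Candidate sets are generated directly from the truth, bypassing the
alignment phase.  Scores are constructed to *be* what the model assumes
they are: decoy scores are drawn from a discrete Gaussian on the integers
(sd 15 by default) truncated at the cutoff, and true-alignment scores from
its exponential tilt by `exp(s/T)`, which for a lattice Gaussian is the
same distribution shifted up by `sd²/T` (45 score units at the default
`T = 5`).  The signal center is the expected gapless alignment score of a
100 bp read under the substitution scoring matrix (match +7 / mismatch −22
at 1% error, `S_xy = round(T·ln(M_xy/(A_x·B_y)))`).  The cutoff defaults to
2.5 sd below the signal center; decoy counts are Poisson (rate 1 per read
by default) at uniform positions.  Under this construction the model
posterior is the exact Bayes posterior of the generative process, so the
calibration test checks the implementation rather than a hopeful
approximation; decoys score below true alignments on average (the tilt
shift is three noise sd), as real sub-optimal hits do.

What the generator does **not** emulate: indel errors and gapped
alignments (candidates are gapless and full-length), decoys clustered in
repeats (they are uniform), adapter contamination, chimeric fragments, and
reference bias.  Passing tests therefore demonstrate correctness of the
pairing mathematics and robustness of the estimators on model-faithful
data, not end-to-end accuracy on real libraries, which depends on the
upstream aligner.

## Evaluation

Predictions are first filtered to mismap ≤ 0.5 (above that a read could
carry several qualifying alignments).  A prediction is counted correct
when chromosome and strand match the truth and the reference intervals
overlap by at least one base (configurable); sweeping the threshold over
the distinct mismap values yields the fraction-correct / fraction-wrong
curve, monotone in both coordinates.  For *calibration* checks the
correctness criterion is the exact source interval (`min_overlap` = read
length), because the posterior is a probability of the exact source, and
the 1-base-overlap criterion occasionally credits a decoy that grazes the
true interval.

Study-condition sizes (chosen to keep the full suite around a minute while
leaving estimator noise well inside the asserted bands): 1000 random
instances for the oracle-equivalence sweep, 1e5 draws for estimator
recovery, 25 000 pairs (~1e5 candidates) for calibration against 99%
binomial bounds per bin, 10 000 pairs for the pairing-benefit and
40%-shuffle comparisons.  The shuffle comparison holds seeds fixed so the
still-conjoint reads see identical candidates in both runs; their accuracy
drop measures exactly the effect of pairing with re-assigned mates.

## Known limitations

* The cutoff correction is a bound-style heuristic; mismaps at the `w/Z`
  scale are conservative rather than calibrated (run with the correction
  off when calibration of very small mismaps matters more than protection
  against sub-cutoff truths).
* Gapless, full-length candidate geometry in the simulator; the I/O layer
  accepts gapped MAF/tab records, but block structure beyond the outer
  coordinates is not used by the model.
* Uniform-position priors ignore chromosome-end edge effects (a fragment
  cannot start within `f` of the end); negligible for `f ≪ L`.
* One log-normal for RNA fragment spans; true intron-length distributions
  are multi-modal.
* `estimate_disjoint_prior` needs uniquely-mapping pairs; repeat-heavy
  data with few unique pairs falls back to the default.
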