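# Methods

This note documents the statistics `ontqc` computes, the defaults it
ships, the design choices that were genuinely open, and what the
synthetic fixtures do and do not establish about real data.

## Read-set statistics

**Nx.** For a multiset of element lengths, Nx is the length at which the
descending cumulative sum first reaches x% of the total. N50 is applied
to read sets, N99 to assemblies (contiguity: higher N99 means less
fragmentation). The implementation is a sort + cumulative scan; the test
suite checks it against an independent brute-force scan on random
multisets up to 10⁴ elements.

**Read quality.** A read's quality is the Phred-scaled mean error
probability, Q = −10·log₁₀(mean 10^(−qᵢ/10)) — the convention of
long-read QC tools, which weights a read toward its worst bases. For a
read set two summaries are reported side by side, because published
"mean read quality" tables rarely state the convention: the arithmetic
mean of per-read Q values (`mean_read_q`, labelled in `q_definition`)
and the all-bases-pooled alternative (`mean_base_q_pooled`). The
filter's Q7 threshold corresponds to a mean per-base error probability
of 10^(−0.7) ≈ 0.20, i.e. roughly 80% accuracy; both filter thresholds
(length ≥ 10 000 b, quality ≥ 7.0) are inclusive, and length is tested
first when attributing rejections.

**Subsampling.** Coverage subsets use shuffle-then-fill: a seeded
permutation of the reads is consumed until the cumulative base count
first reaches target_cov × genome_size. Unlike per-read coin flips this
meets the target exactly once reached, and the subset is a deterministic
function of (input order, seed).

## Mapping completeness

For each read the terminal clipped bases (CIGAR S and H ops at either
end) are divided by the full read length; completeness is one minus the
mean of this ratio over reads. Choices:

- **Primary alignments only.** One observation per read; secondary and
  supplementary records would double-count (toggleable via
  `count_supplementary`).
- **Hard clips count as clipped** and their lengths are added back into
  the denominator, since the original read includes them even though the
  record does not store the bases (`count_hard_clips=False` restricts to
  soft clips).
- **Unmapped reads** are excluded from the mean and reported as
  100·unmapped/(unmapped + primary mapped) percent, matching the
  convention of quoting the unmapped percentage separately.
- A mapped record with a `*` CIGAR is retained by the reader but flagged
  unusable; the statistic counts it as skipped rather than silently
  dropping it.

PAF input is supported when records carry a `cg:Z:` tag; since PAF
CIGARs cover only the aligned query interval, the reader synthesizes
terminal S ops from qstart/qlen so the clip accounting is dialect-free.

## Telomere detection

The motif set {TTAGGG, CCCTAA} is its own reverse complement, so both
orientations are counted as one signal and end classification is
strand-symmetric (a property test reverse-complements contigs and
checks invariance). Matching is exact; N matches nothing. The
sliding-window track uses bin 100 b / step 25 b by default, counting
occurrences fully contained in each half-open window; windows advance
until one reaches the contig end, where it is truncated.

Declaring an end "telomeric" needs a quantitative rule, and none is
standard. The default — ≥ 5 exact motif copies fully inside the
terminal 1000 b — was chosen from the two regimes it must separate: a
genuine telomere tract covers windows densely (a fully repeat-covered
100 b window already holds 16 copies), while the expected number of
exact 6-mer matches in 1 kb of random sequence is about
2·995·4⁻⁶ ≈ 0.49 per strand pair. Both knobs are CLI flags; the
defaults are an explicit operating point, not an inference about any
particular published analysis. Contigs known to be mtDNA or pure rRNA
are excluded by an id list supplied by the user — identifying them
requires annotation outside this package's scope — and excluded rows
remain in the report, flagged, without contributing to totals.

## Coverage triage

Per-contig mean depth sums reference-consuming aligned bases (M/=/X
only; D/N advance without read support — a deliberate choice, since
deleted reference bases have no reads under them) over primary
alignments, divided by contig length.

The "plateau" of true nuclear contigs is estimated robustly rather than
by eye: take contigs ≥ 50 kb with positive depth, compute their
length-weighted median depth m, keep those within [0.5m, 1.5m], and
return their length-weighted mean. Length weighting makes the estimate
insensitive to how an assembler happens to split chromosomes; the band
discards mtDNA-like and artifact-like outliers before averaging. On the
worked example (5 Mb@100×, 4 Mb@98×, 0.2 Mb@40×, 0.05 Mb@400×) this
yields (5·100 + 4·98)/9 ≈ 99.11×.

Classification: depth < 0.67 × plateau ⇒ artifact (strict inequality: a
contig exactly at the cutoff is kept), depth > 2 × plateau ⇒ high-copy,
else true. The rule is scale-invariant and every constant is a flag.
This cutoff is a deliberately naive screen — in genomes with segmental
duplications or uneven complexity it should be reviewed manually, and
the CLI accepts `--plateau` to override the estimate.

Window-level uniformity flags use median + 3 × (1.4826·MAD); a mean/SD
rule would let a single rRNA-array spike inflate the scale it is judged
against. When the MAD is zero (most bins identical) any bin strictly
above the median is flagged.

## Indel profiling

Reference genes (e.g. conserved single-copy orthologs extracted from a
BUSCO run, supplied by the user) are globally aligned to their assembly
copies with a Gotoh affine-gap dynamic program written for this package.
A gap of length L costs gap_open + L·gap_extend; defaults
(+1/−2, −4/−2) make one 2-base gap (−8) cheaper than two 1-base gaps
(−12), so real multi-base indels surface as single events. Setting
gap_open = 0 gives the linear-gap limit, which the tests compare against
a plain Needleman–Wunsch oracle; affine scores are cross-checked against
Biopython's PairwiseAligner (whose first-base/extension convention maps
to ours via open' = gap_open + gap_extend). Traceback tie-breaking is
fixed — diagonal, then gap-in-assembly, then gap-in-reference, with gap
extensions preferred over re-opening — so alignments are reproducible.
Memory is one byte per DP cell; gene-scale inputs (≤ ~20 kb) are the
intended regime.

Indels are maximal gap runs, polarized relative to the reference
(sequence A): bases present only in the assembly are insertions, bases
missing from it deletions. An event is **homopolymeric** when its bases
are a single repeated base b and the maximal run of b in the reference
touching the event site, plus the event bases themselves, reaches
min_run = 3 (a flag; no standard definition exists, so the threshold is
an explicit parameter rather than an implicit convention). Everything
else is random. n_homo + n_random always equals the number of extracted
events.

## Synthetic fixtures

Generators are pure functions of (parameters, seed) built on numpy's
PCG64; identical calls give byte-identical fixtures, and no global
random state is used. Defaults mirror the regime the analyses target:
log-normal read lengths with median ≈ 16 kb, per-read quality around
Q12, ~100× plateau depth with planted ~30× artifact and ~400× high-copy
contigs, Beta-distributed clip fractions, and exact tandem telomere
arrays. Per-base quality jitter is a separate `base_sd` parameter
(default 0) so that a zero per-read spread reproduces the target mean
quality exactly.

What they deliberately do not model: ONT error profiles (no
quality-by-position decay, no systematic homopolymer truncation in the
reads themselves), chimeric or adapter-bearing reads, GC-coverage bias,
and repeat-induced mapping ambiguity. Planted indels are isolated
(≥ 10 b apart, random events kept away from homopolymer runs), so exact
planted-truth recovery shows the alignment-and-classification machinery
is correct — not that indel calling is unambiguous in tandem-repeat
regions, where equivalent gap placements genuinely exist. Passing tests
therefore validate the computations, not the biology of any particular
dataset.

## Problem sizes and numerics

The test and acceptance workloads are desk-scale by design: 10³–10⁴
reads or alignments, kilobase-to-10 kb sequences, 1000-multiset Nx
sweeps, 200-pair alignment oracle checks. All depth, Nx and clip
arithmetic is exact integer or double-precision work with no iterative
optimization; the only tolerances in the suite are 1e-12 for
oracle-equivalence of alternate implementations and 2 standard errors
for recovering planted stochastic parameters. Degenerate inputs have
defined behavior throughout: empty streams raise informative errors,
all-zero depth tracks flag nothing, contigs shorter than the end window
evaluate both (overlapping) ends, and boundary values at every
threshold are documented as inclusive or strict at the function level.
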