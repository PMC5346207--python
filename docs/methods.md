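# Methods

`scaffmap` implements the map-guided procedure used to turn a fragmented
whole-genome-shotgun assembly into chromosome-scale pseudomolecules, and
the recombination analyses that such an assembly enables. This note
documents the models, the defaults and why they were chosen, the
numerical details, and what the synthetic benchmark does and does not
demonstrate.

## Marker placement

Markers reach the sequence by one of two routes, mirroring how mapped
markers carry either primer pairs or flanking sequence.

**In-silico PCR.** A primer pair amplifies a locus when the forward
primer matches one strand and the reverse primer matches the opposite
strand downstream, with the product length inside a configurable window
(default 80–600 bp). Matching is substitution-only (no indels), with a
per-primer mismatch budget; the 3' terminal base of each primer must
match exactly, since a mismatched 3' end prevents polymerase extension.
Ambiguity bases (N) in the template never count as matches. Placement
runs three successive rounds with budgets 0, 1 and 3; a marker is
accepted at the first round yielding exactly one product. Uniqueness is
evaluated per round, not cumulatively — an early, stricter round that
resolves a single locus wins even if later rounds would add spurious
near-matches. Matching is implemented by pigeonhole seeding (with k
mismatches allowed, one of k+1 primer chunks must occur exactly) and
verified candidate-by-candidate; a brute-force window scan serves as the
test oracle.

**Flank search.** Markers carrying a ~150 bp flanking sequence (or whose
primers found no unique product) are located by banded semi-global edit
distance (edlib, infix mode) with defaults min identity 0.90 over at
least 0.80 of the query; hits within one query length collapse to the
best per locus. Markers with multiple loci at every stage are rejected
as multi-locus; markers with none are rejected as unplaced.

**Quality filters.** Sequencing-derived SNP candidates are kept when
site coverage lies within [0.5×, 2×] of the mean (computed excluding
zero-coverage regions), minor-allele frequency exceeds 0.30, the site
Phred quality is ≥ 20 and the mean quality of the 11 bp window is ≥ 15;
each discard records the first failed rule. Array genotypes are retained
at GeneTrain score ≥ 0.4 with missing fraction strictly below 0.10;
records whose progeny segregation contradicts the parental genotypes
(identical homozygous parents with heterozygous progeny) are flagged
rather than silently dropped.

## Chromosome assignment, chimera breaking, ordering

Scaffolds are assigned to chromosomes by majority linkage group over all
placed mapped markers, full and bin level voting equally. Bin-mapped
markers (genotyped on a minimal progeny subset) suffice for assignment
but are excluded from ordering and orientation — they carry no usable
within-group recombination signal.

A scaffold is a chimera candidate when its physically ordered
fully-mapped markers split into adjacent blocks of at least 2 markers
belonging to different linkage groups, or to the same group with a cM
discontinuity above 10 cM across less than 20% of the scaffold length.
A lone discordant marker never triggers a break; it is flagged suspect
(putative paralogue or mismapped marker) and excluded downstream. The
break interval spans the innermost discordant markers; the break point
is the midpoint of the longest N-run inside the interval, else the
interval midpoint. N-runs are the assembly-intrinsic proxy for weak
joins: scaffolds join contigs across gaps of estimated size, and a
misjoin is overwhelmingly likely to sit at such a join rather than
inside a contiguous contig. Broken pieces get deterministic derived
names recorded in a rename ledger; concatenating the pieces reproduces
the original sequence exactly, and placements are re-coordinated onto
the pieces (placements spanning a cut are dropped).

**Ordering.** Genetic positions from different maps are not directly
comparable (total map lengths differ by tens of cM), so per-map cM is
first rescaled to [0, 1] within its linkage group. A scaffold's
consensus position is the marker-count-weighted mean over maps of the
per-map median rescaled cM of its fully-mapped concordant markers.
Because the rescaling leaves small affine offsets between maps, the
consensus value alone can invert nearly-tied neighbours when they are
supported by different map subsets; the order is therefore refined by a
bubble pass in which adjacent scaffolds are compared *within* each map
that covers both (sign of the difference of median cM, marker-count
weighted) — within-map comparisons are offset-free. Ties in consensus
position are broken by scaffold length descending and flagged "order
uncertain".

**Orientation.** Each map with at least two distinct cM values on a
scaffold votes with the sign of its Spearman correlation between
physical position and cM; votes are combined weighted by the number of
distinct genetic positions. Cross-map pooling of points is deliberately
avoided for the same offset reason as above. Scaffolds where no map
resolves two genetic positions (markers cosegregating, e.g. inside the
centromeric region) are emitted as orientation "unknown"; when maps
disagree the better-resolved map wins and the call is flagged
"conflict".

**Pseudomolecules.** Ordered, oriented scaffolds are concatenated with
exactly one spacer of 10,000 N between consecutive components; unknown
orientations enter as '+' but are written with AGP orientation '0'.
Output is AGP v2.1 (1-based inclusive; U components with gap type
"map") plus FASTA; rebuilding the FASTA from the AGP and the source
scaffolds is byte-identical by construction and asserted in tests.

## Gap patching and variant polishing

A gap is a maximal N-run of length ≥ 10 (the same threshold defines
"contig" in the metrics module, so contig counts are consistent across
stages); AGP "map" spacers are never patch targets. A contig may close a
gap when both of its ends align to the sequence flanking the gap with
≥ 95% identity on each side and at least 1/3 of the contig length
anchored in total. The published wording of the 1/3 rule is ambiguous
between a combined and a per-side reading; the combined fraction is the
default (the more inclusive reading) and `anchor_mode="per_side"` gives
the stricter one. Flank alignment is local (match +1, mismatch −1, gap
open −2, extend −1) against windows of twice the contig length (capped
at 50 kb) on each side, in both contig orientations; the window-side
alignment must reach within 10 bp of the gap edge. An exact 15-mer seed
prescreen skips contig × gap pairs sharing no seed with the 1 kb
immediate flanks — unrelated pairs essentially never share a 15-mer,
while any contig able to pass the 95%-identity rule shares many. Per
gap, the eligible contig maximizing anchored fraction × mean identity
wins; ties break by longer contig then lexicographic id; one contig may
close only one gap (greedy by score), preventing double use of a
repeat-borne contig. The N-run is replaced by the contig's unanchored
middle — the insert length may legitimately differ from the N-run
length, and the implementation never assumes they agree.

Variant polishing applies VCF records that are homozygous-alternate
with PASS/empty filter, in coordinate order with cumulative offset
tracking so downstream positions stay valid after indels. REF
mismatches and overlapping records are skipped and counted, which makes
a second pass a no-op (idempotence, asserted in tests). Counts are
partitioned SNP vs indel by REF/ALT length.

## Contiguity metrics

The N50/L50 naming follows the convention of the genome releases this
package models: N50 is the *number* of sequences whose cumulative
length reaches half the assembly, L50 the *length* of the sequence at
that point — the reverse of common usage. `n50_l50(..., conventional=True)`
swaps the pair for interoperability. Percent values are rounded to one
decimal for display; full precision is kept internally.

## Recombination analysis

Marey maps (genetic vs physical position of uniquely anchored,
fully-mapped, non-suspect markers) are fitted with cubic smoothing
splines; the smoothing parameter is selected by ordinary leave-one-out
cross-validation over a log-spaced grid scaled to the cube of the
physical span (generalized cross-validation is available as the
non-CV branch). Duplicate physical positions are averaged before the
fit. The recombination rate is the spline's first derivative on a
uniform 200-point grid, clamped at zero — points are not reordered or
dropped, since discordant markers are already handled upstream as
suspects. The integral of the clamped rate over the span, relative to
the observed cM span, is reported as a fit diagnostic (within 10% on
all benchmark chromosomes).

A putative centromere is the longest contiguous grid region with rate
below 0.1× the chromosome mean spanning at least 2% of the chromosome.
Only the recombination-suppression criterion is implemented, so calls
are "putative centromeric intervals"; confirming repeat content or
transcript deserts is out of scope.

Whole-chromosome recombination rates are cM span / Mb span per map and
chromosome, with totals from summed spans. The multi-map comparison
excludes chromosome entries covering less than 50% of the
pseudomolecule (their ratio reflects a local, not chromosome-wide,
rate) and always computes both branches: one-way ANOVA with the Tukey
post-hoc, and tie-corrected Kruskal-Wallis with pairwise Mann-Whitney
under Bonferroni; Levene (mean-centred) and per-group Shapiro-Wilk at
α = 0.05 decide which branch the assumptions endorse. With unequal
group sizes the Tukey standard error uses the harmonic mean of all
group sizes (the classic unequal-n form, as in the PAST statistics
package, which this module reproduces cell-for-cell on the packaged
reference table); the Tukey-Kramer per-pair form is available via
`tukey_kramer=True`. Mapping functions: Kosambi
d = 25·ln((1+2r)/(1−2r)), Haldane d = −50·ln(1−2r), and
Haldane→Kosambi conversion through the implied recombination fraction.

## Synthetic benchmark

The generator builds a deterministic truth genome: by default 8
chromosomes of 0.8–1.2 Mb (a ~200× scale-down of a typical compact
plant genome, so the full benchmark runs in minutes on one CPU), GC
0.38, and a monotone Marey function per chromosome constructed as a
PCHIP interpolant through random increasing control points with a
forced zero-slope plateau over a centromeric interval of 15% of the
chromosome placed at 35–65% of its length; map lengths are drawn from
45–80 cM. By construction the Marey function is continuous,
non-decreasing, flat exactly on the plateau, and integrates to the
configured map length.

The scaffold set (default 40 scaffolds) plants three defect classes
with recorded truth: interchromosomal chimeras (2 segments from
different chromosomes, junction recorded), wrongly oriented scaffolds
(reverse-complemented, strand recorded), and unplaced scaffolds (the
shortest pieces, excluded from marker sampling). N-run gaps (default
30, run lengths 50–500) replace truth intervals of *different* length
(inserts 100–800 bp), so gap size ≠ insert size as in real assemblies.
Gaps are planted on plain scaffolds only, so each planted defect
exercises exactly one repair path. Four linkage maps of different
density (45/60/15/25 markers per chromosome) emulate a multi-map study
design; marker cM is the truth Marey value plus optional Gaussian
noise, a configurable fraction is bin-level, and mismapped markers
(wrong linkage group) can be planted and are recorded. The benchmark
conditions used by the acceptance checks are the defaults with zero cM
noise and no mismapping: they test the machinery's exactness, not its
noise robustness (noise behaviour is exercised separately in unit
tests).

Patch contigs copy the true insert flanked by exact flank copies sized
to clear the 1/3 rule; decoys fail in exactly one recorded way:
flanks mutated at 10% (below the 95% identity bar even after local
alignment trims ends), a long unanchored middle (anchored fraction
< 1/3), or one-sided anchoring. Planted variants are homozygous SNPs
and short indels (1–6 bp), ≥ 10 bp apart, outside N-runs, with the
correction VCF recorded so that applying it must restore the
pre-corruption sequence byte-for-byte.

**What the benchmark does not show.** Sequences are i.i.d. random: no
repeats, no compositional bias, no heterozygosity. Real genomes place
multi-locus markers, repeat-borne contigs and paralogous SNPs in the
pipeline's path far more often; the quality filters and uniqueness
rules exist for those cases but are exercised here only through
constructed examples. Read-level effects (sequencing error, coverage
variation) are out of scope — maps and VCFs are inputs, not inferred
from reads. Perfect recovery on the benchmark therefore validates the
bookkeeping, thresholds and numerics, not performance on repeat-rich
real data.

## Numerical details and edge cases

- All randomness flows through `numpy.random.default_rng` seeds; every
  stage seed derives from one pipeline seed via `SeedSequence.spawn`.
  Identical config + seed reproduces byte-identical FASTA/VCF/tables.
- Exact counts (bin fraction, mismap rate, spanning fraction) use
  `round(n·f)`, so stated fractions are hit exactly at any n.
- Spearman/Kendall statistics on constant vectors return NaN; such
  scaffolds become orientation "unknown" rather than propagating NaN.
- `chromosome_cmmb` marks entries with missing physical span
  unavailable (NaN) and excludes them from group comparisons.
- Scaffolds with zero fully-mapped markers are appended after ordered
  scaffolds on their chromosome and flagged "unordered".
- Break positions at 0 or at sequence length are input errors; a break
  event bisecting nothing (empty interval after evidence merging) is
  dropped.

## Known limitations

- The chimera detector keys on marker discordance; a chimera whose
  second segment carries fewer than 2 fully-mapped markers is
  undetectable by design (matching the ≥ 2-marker evidence rule).
- The same-linkage-group discontinuity rule (jump > 10 cM within < 20%
  of the scaffold length) can fire on a clean scaffold where a steep
  map interval meets locally sparse fully-mapped markers. This is a
  scale effect: the synthetic genome packs 45–80 cM into ~1 Mb, an
  order of magnitude denser in cM/Mb than a typical real genome, so a
  10 cM gap between physically close markers is occasionally
  legitimate here while it almost never is at real scale. The
  benchmark conditions used by the acceptance checks show zero false
  breaks; other seeds may show one, and the thresholds are exposed in
  the configuration for rescaled studies.
- Orientation of scaffolds entirely inside a recombination-suppressed
  region is genuinely indeterminate; they are reported "unknown", never
  guessed.
- The flank aligner assumes gap flanks are unique at the 15-mer level;
  on repeat-rich real data a repeat-masking step (out of scope here)
  would be required upstream, and the one-contig-one-gap rule is the
  only guard against repeat-borne double use.
- Map comparison treats per-chromosome ratios as independent
  observations within a map, as the published analysis does; no
  phylogenetic or shared-pedigree correction is attempted.
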