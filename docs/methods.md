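# Methods

## The screening problem

A young isoform transcribed from its own promoter can be lost by any
mutation that removes the promoter, the splice donor of its dedicated first
exon, or the exon's ability to encode protein. The package screens an
aligned orthologous region — promoter block, TSS block, 5'UTR, first-exon
coding block, splice donor — for such lesions, converts the lesion inventory
into a functional/lost/unknown verdict per species, and maps the verdicts
onto a rooted species tree to count independent loss events.

All detectors are deterministic functions of (species row, reference row,
annotation). Coordinates are 0-based half-open alignment columns internally
and 1-based inclusive in every human-readable table.

## Lesion detectors and their thresholds

- **Start codons.** The three row bases at the annotated reference columns
  must read exactly ATG. A gap makes the codon `-`-padded and not intact; an
  N makes the status *ambiguous* (unknown downstream) rather than lost.
  Intact ATGs are graded on the two Kozak positions with dominant effect:
  −3 purine and +4 G (both → strong, one → adequate, none → weak). Kozak
  weakness is reported but never counts toward loss: context quality is
  positive evidence of functionality, not a lesion.
- **ORF disruptions.** Indel runs are maximal gap runs of the row against
  the reference (and reference-gap insertion runs); a run inside the coding
  block whose ungapped length is not a multiple of 3 is a frameshift. Stops
  are read from the row's consecutive ungapped bases starting at ATG1's
  column — reading consecutively is what shifts the frame downstream of an
  indel, so no separate frame bookkeeping is needed. The frame is anchored
  at ATG1's column even when ATG1 itself is mutated (frame conservation is
  scored independently of start-codon status). Every in-frame stop strictly
  before the donor is reported. A fully gapped coding block collapses to a
  single `region_absent` lesion; so does a fully gapped region, in which
  case no other lesion objects are emitted (one event, one cause).
- **Splice donor.** Intact iff the two bases at the donor position read GT.
  Any substitution — including the naturally occurring GC variant — counts
  as loss; gaps mean the donor was deleted; N is unknown.
- **Promoter.** Only indels are scored: *absent* when ≥ 90% of the promoter
  block's reference bases are gapped; *rearranged* when a deletion ≥ 30 bp
  overlaps the TSS block or an insertion ≥ 30 bp lies within it. The 30 bp
  threshold sits well below the attested 72 bp muroid insertion and well
  above alignment jitter. Substitution-level promoter divergence is not
  scored: no computable metric separates tolerated divergence from loss, so
  the screen is conservative there (an open limitation).

## Calling rule

lost ⇔ promoter rearranged/absent ∨ donor lost ∨ both ATGs mutated ∨
any frameshift/premature stop ∨ region absent. A lone start-codon loss is
tolerated because translation of constructs carrying only ATG2 initiates
efficiently at that site. Low-coverage rows are unknown and are excluded
from event counting rather than imputed. The verdict is monotone (adding a
qualifying lesion can only move functional → lost) and order-invariant.

## Dollo mapping and lesion-aware splitting

The isoform is gained once (present at the root); losses are the only state
changes. The minimum event set is the set of maximal clades whose leaves
are all lost-or-unknown and which contain at least one lost leaf; unknown
leaves are wildcards inside lost clades and never anchor events. Among
tying placements the event is anchored at the stem of the MRCA of its lost
leaves — the placement closest to the terminal lineages. If every leaf is
lost-or-unknown the single root event is returned flagged, since it
contradicts presence at the root.

Events are then split by lesion compatibility: leaves are grouped by the
transitive closure of pairwise lesion homology, where two lesions are
homologous iff same type + overlapping span (+ identical ungapped length
for indel types, with zero overlap tolerance). Splitting can only increase
the count. Homologous-looking lesions in separate events (e.g. the same
donor dinucleotide substituted on two distant branches) are flagged
`homoplasy` and left independent; they are never used to revise the tree.

## Expression classification

Counts are normalised to per-bp densities. The package's coverage
convention makes the control exon's density the **mean** of the two
first-exon densities, so the coherence deviation is
|d_1A + d_1B − 2·d_6| / (2·d_6) (default tolerance 20%, configurable, and
computable on raw counts instead by supplying exon lengths of 1). Under
equal molar expression the expected split of N = reads_1A + reads_1B is
length-proportional (228:245), not 50/50 — required for consistency with
per-bp normalisation. The Pearson statistic over the two cells has 1 df.
Bonferroni (p_adj = min(1, m·p)) is used for the family correction as the
most conservative standard reading of "corrected for multiple tests";
m defaults to the family size (7 in the motivating dataset). The detection
floor for single-isoform calls is 2% of the control-exon density: low
enough that a library with tens of minor-isoform reads is tested rather
than declared single-isoform, while truly silent isoforms (zero or a
handful of reads against thousands) still fall below it.

## Scanning model of initiation

Ordinal, not quantitative: band intensities in the motivating assay are
qualitative. Candidates are all ATGs plus near-cognate codons (one
substitution from ATG) in strong context. Products require the candidate
to be in frame with the reporter. Rules: first potent (strong/adequate)
ATG → strong; later in-frame ATGs → leaky; near-cognates → faint, and only
when no intact ATG lies upstream; reporter-internal ATGs → background, and
only when no potent upstream ATG exists. Re-initiation beyond the second
site and RNA structure effects are not modelled. The packaged archetype
constructs are synthetic stand-ins built to the described features: ATG1,
ATG2 two codons downstream, AAG three codons after ATG1 in strong context;
engineered ATG knockouts use two-substitution codons so the knockout does
not itself create a near-cognate site.

## Synthetic data and what it does (not) show

The template region is 872 alignment columns: 500 promoter columns, a
152-column TSS block containing a 72-column reference-gap insertion pool,
a 28-nt 5'UTR ending in GCCACC, 60 codons starting ATG GCC ATG AAG, the GT
donor and 10 intronic bases. Neutral evolution applies point substitutions
only (per-site probability 1 − e^(−rate·branch length)); alignment columns
are preserved, start codons and the donor are immutable, and coding
substitutions that would create an in-frame stop are skipped, so planted
truth tables are exact. `protect=False` exists for stress testing and is
excluded from exact-recovery guarantees. Lesions are planted per branch
and inherited identically by all descendant leaves (insertion bases drawn
once per spec). Loss-sufficient lesions on nested branches are rejected as
input errors because the truth count would be ill-defined.

Recovery scenarios draw 1–7 distinct archetypes (promoter deletion,
promoter insertion, region absence, donor loss, frameshift, premature
stop, double-ATG loss) on disjoint branches of a 14-taxon tree at
background rate 0.05. The planted stop archetype sits upstream (codon 8)
of the frameshift archetype (codon 15) so frameshift-induced downstream
stops can never span-overlap a planted stop and spuriously merge two
events that happen to be sister clades.

Read counts: the expected first-exon total ("depth") splits multinomially
with probabilities ∝ molar level × exon length; totals are Poisson, or
negative binomial (var = μ + dispersion·μ²) when overdispersed. The
`expected_counts` helper returns the exact expectations (at ratio 1 and
depth 473 they are 228/245/426, the length split).

The packaged survey fixture (18 taxa) transcribes only text-attested
states; figure-only muroid taxa are packaged as low-coverage placeholders
(unknown, wildcards that do not inflate the count). Its coding block is
excluded from background substitution so the lesion inventory — and the
7-event result — is invariant to the seed, which only varies neutral
promoter/UTR divergence.

What passing tests show: the detectors, caller, Dollo minimiser and
splitter are exact on data generated under the package's own conventions
(clean alignments, point-substitution background, clade-faithful lesions).
What they do not show: robustness to alignment error, lineage-specific
rate variation, indel polymorphism within clades, partial assemblies
beyond a binary coverage flag, or promoter divergence without indels —
real-data failure modes that the screen either flags as unknown or simply
cannot see.

## Problem sizes used by the checks

Exhaustive Dollo verification covers every rooted binary tree with up to 6
leaves (1,069 topologies) under all functional/lost assignments against an
independent Sankoff-style DP oracle. Recovery uses 200 seeded scenarios;
null calibration uses 143 seven-library families (1,001 libraries) at
depth 5,000; power uses 400 libraries at an 8-fold B excess and depth
2,000; p-value uniformity uses 10,000 multinomial draws with a KS distance
bound of 0.03 (allowing for count discreteness).

## Known limitations

- Pre-oriented, pre-aligned inputs are assumed; no reverse-complement or
  realignment handling.
- The independence proxy (type + span + length) can over-split genuinely
  homologous lesions whose aligned spans drifted apart, and cannot detect
  independent recurrences at identical positions within one clade.
- Dollo's single-gain premise is taken from the biology (the isoform arose
  once); the mapper reports, but does not test, that premise.
- The initiation model is ordinal and ignores context beyond −3/+4.
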