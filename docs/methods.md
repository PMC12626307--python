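# Methods

## Coordinates and data model

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read and restored on write, refFlat and
BED/bedGraph are read as-is. A gene is the union of its isoforms'
exon structures; the merged, disjoint `exon_union` defines both the exonic
territory used for `C1` and, by complement, the *independent introns*: gaps
between consecutive union intervals, which by construction overlap no exon
of any isoform. When an annotated intron of one isoform contains another
isoform's exon, the sub-intervals flanking that exon are separate gaps of
the union and each is treated as an independent intron in its own right,
with the nearest union boundary as its transcript-5′ exon end — the choice
that maximizes recall while honouring the non-overlap requirement. Genes
whose isoforms span multiple chromosomes or strands are rejected with a
warning. Overlapping genes are processed independently: an intron of gene A
that overlaps an exon of gene B is still independent *for A*, because the
rule is per-gene.

A deliberately strict reading is used for "intronic": a candidate region
must avoid the exons of *all* isoforms. The permissive alternative (intronic
in at least one isoform) would admit regions that are exonic elsewhere and
make `C2` uninterpretable as truncation signal.

## Candidate catalog

Candidate cleavage positions are the union of three evidence tiers, each
restricted to independent introns:

| source | default parameters | notes |
| ------ | ------------------ | ----- |
| `db`   | single-base BED positions (longer features → midpoint) | annotated polyA-site databases |
| `peak` | min_reads = 5, merge_gap = 24 nt | single-linkage clustering of 3′-most aligned bases; summit = modal position, ties leftmost |
| `pas`  | motifs {AATAAA, ATTAAA}, cleavage offset +21 nt | sense-strand hexamer scan; an optional flag adds the 1-mismatch neighborhood of AATAAA (19 hexamers) |

The PAS-to-cleavage offset of 21 nt is the midpoint of the canonical
10–30 nt spacing between the signal hexamer and the cleavage site; it is
configurable, as are the peak-calling parameters, since no reference
procedure exists for either. Sites from different tiers within 50 nt on the
same strand are merged, keeping the highest-priority source
(db > peak > pas); 50 nt matches the ±50 bp evaluation tolerance so that a
merged site can never be counted as two events.

## Coverage

Coverage sources share a single `fetch(chrom, start, end)` interface with
three backends: BAM (via the per-base pileup of primary, non-supplementary
alignments, MAPQ ≥ 0 by default, duplicates excluded but flag-configurable),
bedGraph (interval expansion, absent bases = 0), and in-memory arrays
(simulation). Spliced alignments contribute only M/=/X bases — N gaps are
excluded, which is essential: intron-spanning reads must not inflate
intronic depth. Coverage is strand-agnostic by default because most bulk
libraries are unstranded; a `stranded` option restricts BAM counting to one
orientation.

## Event calling

Per gene, `C1` is the mean depth over `exon_union`; genes with `C1 = 0` are
skipped. Per candidate site, Type 1 is attempted first and Type 2 only if
Type 1 fails, mirroring the biological precedence (a retained intron
explains the coverage without invoking an unannotated exon). Filters, with
defaults and rationale:

* `TR ≥ 0.2` and `C2 > 10` — the published operating point of the method;
  both configurable.
* **Downstream drop** (Type 1): the mean depth over the 100 nt downstream
  of the site must fall below 0.5 × C2. A polyA site implies transcripts
  end there; a uniformly covered (fully retained) intron is not an IPA
  event. The window and fraction are declared defaults — the underlying
  idea (a visible drop near the site) does not by itself quantify either.
* **Junction contiguity** (Type 1, this package's own guard): the first
  100 nt of the retained-intron window, adjacent to the upstream exon, must
  average ≥ 0.5 × C2. Without it, a Type 2 profile (gap + high block) can
  satisfy the window-mean and drop checks through dilution and be mistyped
  as Type 1.
* **Cryptic exon** (Type 2): the longest coverage suffix ending at the site
  with mean ≥ 0.8 × C1, refined by trimming edge bases below 0.5 × C1
  (a long mean dilutes slowly, so the unrefined longest suffix overshoots
  into the gap), length within [50, 2000] nt, and preceded by ≥ 50 nt with
  mean < 0.2 × C1 separating it from the upstream exon. The length bounds
  and gap rule are guards against degenerate blocks; all are configurable.

At most one event is reported per independent intron — the highest-TR
candidate, ties to the most upstream site (the earliest truncation).
TR is a within-sample ratio and needs no cross-sample normalization; it is
invariant under uniform depth scaling, which the test suite asserts.

## Differential usage

Without replicates, each event called in either sample gets a 2×2 table
(condition × [intronic terminal-region count, exonic count]) where counts
are total aligned bases in the region divided by the read length
(configurable), tested with Pearson's chi-squared (1 df, no continuity
correction; a zero marginal returns p = 1 with a warning). With replicates,
per-replicate TRs — recomputed at the same coordinates in every replicate,
never zeroed for samples where the event was not independently called — are
compared with a two-sided Wilcoxon rank-sum test. Significance always
requires both `p < 0.05` and `|TR1 − TR2| > 0.2`; p-values are reported raw
by default, with optional Benjamini–Hochberg adjustment.

The exact rank-sum null is enumerated (midranks, so ties are handled) when
both groups have ≥ 4 members and the combined n ≤ 10. For triplicate
designs the exact two-sided test cannot reach p < 0.05 — its minimum is
2/20 = 0.1 — so the tie-corrected normal approximation without continuity
correction is the default there; a fully separated 3 vs 3 comparison then
yields p ≈ 0.0495. This choice is deliberate and documented because a
triplicate design is the common case; callers can force either mode.

## Peptide reconstruction

Translation uses the standard nuclear code, stops before the first stop
codon, and renders ambiguous codons as `X`. Type 1 events concatenate the
spliced upstream CDS (transcript orientation, minus-strand genes
reverse-complemented) with the retained-intron sequence up to the site and
translate in the annotated frame — frame inheritance is the coherent model
for a splicing-inhibited extension. Type 2 events append the cryptic-exon
sequence and translate it in all three frames from the cryptic-exon start
(its reading frame is unknowable from annotation), each prefixed with the
annotated upstream peptide. The full truncated protein is emitted with
`novel_tail_start` marking where it departs from the annotated protein.
Among coding transcripts the one contributing the longest upstream CDS is
used; genes without a coding transcript upstream of the event are skipped
with a warning. Selenocysteine and non-standard codes are unsupported.

## Nucleotide composition profiles

Windows of ±50 nt around sites are extracted in transcript orientation
(minus-strand windows reverse-complemented) so "upstream" is biologically
consistent across strands; per-offset frequencies exclude N from the
denominator. Real IPA sites show A/T enrichment upstream dominated by the
PAS hexamer near −21…−16.

## Synthetic benchmark generator

The generator works at coverage level by default: it emits a gene layout
(3–5 exons of 150–300 nt, introns of 900–1800 nt, random strand, ~250 genes
per synthetic chromosome), per-gene expression λ from a Gamma mixture
(shape 3, mean = `mean_depth`), exonic per-base depth ~ Poisson(λ),
intronic background ~ Poisson(0.02 λ), and planted events only in the top
50% expression quantile — low-expression genes make truncation calls
ambiguous, so the benchmark concentrates events where they are resolvable.
Type 1 events elevate the region from the upstream exon boundary to the
site to Poisson(TR·λ) with TR ~ U[0.3, 0.9]; Type 2 events plant a
100–250 nt block of Poisson(TR·λ) with TR ~ U[0.85, 1.0] — Type 2 TRs sit
above the 80%-of-C1 boundary rule by construction, since a cryptic terminal
exon that fails that rule is not a Type 2 event under this model. An AATAAA
hexamer is written 21 nt upstream (transcript orientation) of every planted
and decoy site. Decoy sites (one per sampled non-event gene) provide
negatives for ranking metrics. The paired generator plants Type 1 events
only — a per-condition TR pair must be able to differ by > 0.2 while both
remaining within the detectable range, which the [0.8, 1.0] Type 2 band
cannot accommodate — with the lower TR ~ U[0.25, 0.40], |ΔTR| ~
U[0.25, 0.40], random direction, plus non-differential events at equal TR;
replicates are independent Poisson redraws of the same depth profile. One
seed drives every draw, so runs are byte-reproducible, and scaling
`mean_depth` with the same seed preserves the layout and truth positions
exactly (depth enters only through λ).

Deliberately *not* modeled: read-level artifacts (fragment-length and GC
biases, sequencing errors, misalignment, multimapping), overlapping genes,
alternative isoform structure within a gene, and soft-clipped junction
noise. Consequently the benchmark's separation between true and decoy
candidates is sharper than on real libraries: passing scores here establish
the correctness of the statistical machinery and the geometry of the
caller, not field performance on noisy alignments. The optional read-level
mode decomposes each depth profile into coverage-preserving fragments and
writes a sorted, indexed BAM whose pileup equals the bedGraph profile
exactly; it exercises the BAM code path end to end rather than emulating
sequencer chemistry.

## Evaluation harness

Calls are matched to truth one-to-one within ±50 bp, greedily by distance
(ties: leftmost). Sensitivity is matched truths / all truths; the
false-call rate is unmatched calls / all calls, i.e. 1 − precision (the
benchmark literature for this problem reports that quantity as a
"false positive rate", which is kept here for comparability despite the
nonstandard name). Ranking quality is the rank-statistic AUC,
AUC = P(score⁺ > score⁻) + ½ P(=), with the candidate's threshold-free TR
as score — decoys receive their computed TR even when it fails the filters.
Truth sites are scored at their planted coordinates; the alternative
(treating undetected truths as score 0) would conflate detection and
ranking.

## Benchmark problem sizes

The regression suite and the reproduction script run the full-size design:
1,000 events (500 + 500) among 2,000 genes for the single-sample benchmark
at mean depths 50 and 5, and 1,000 differential + 1,000 non-differential
events among 4,000 genes with 3 replicates per condition for the paired
benchmark (~130 Mb of simulated coverage in total). Coverage-level
simulation makes this cheap: the full reproduction completes in well under
a minute on one CPU.

## Known limitations

* The 2×2-table construction for the unreplicated chi-squared test
  (coverage totals / read length) is one reasonable choice among several;
  it is declared and configurable, not canonical.
* The Type 1 junction-contiguity guard and the cryptic-exon length/gap
  bounds are this package's own guards; disabling them reverts to the bare
  window-mean + drop formulation.
* `C1` uses the exon union of all isoforms; a dominant short isoform can
  therefore depress TR for genes with large isoform diversity.
* Tandem 3′-UTR APA is out of scope by design; only intronic events are
  called.
* Single-cell data are not supported: per-cell coverage is too sparse for
  the per-base profiles the caller relies on.
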