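# Methods

## Coordinates and strand handling

All internal coordinates are 0-based half-open on the contig. GFF3 and any
coordinate quoted from literature are 1-based inclusive and converted at the
I/O boundary (`GenomicInterval.from_one_based`), so a printed span like
16,669,728–16,670,275 has length 548 without internal off-by-one arithmetic.
Minus-strand loci are normalised at load time to a plus-strand working copy —
coordinates mirrored, contig reverse-complemented — so every downstream rule
is written once; `origin_strand` is retained and `denormalize_position` maps
report coordinates back. BED12 is accepted as an alternative transcript
dialect with thickStart/thickEnd as the CDS, since RNA-seq transcript models
commonly arrive that way. The CDS is stored as a genomic span rather than an
(exon, offset) pair; the two are equivalent and the span matches what GFF3
and BED12 provide directly.

## Putative TSS calling

The acceptance rule mirrors how curators treat 5′-end evidence: a transcript
5′ end annotated inside an intron is a putative TSS; an end inside an internal
exon is also accepted (internal, exonic promoters are real), *unless* it
coincides exactly with an ATG — such ends are the classic signature of
truncated cDNAs that begin at the first codon and are rejected as truncation
suspects. Ends at or inside annotated first exons are treated as scatter
around the annotated promoter. This context vocabulary folds "inside a first
exon" into `annotated_start` and "intergenic" into `intronic`; both are
accepted, and only the internal-exonic-at-ATG case is ever rejected.

## Promoter clustering and shape

Accepted TSSs are clustered by single-linkage in one dimension. The gap rule
is strict: a gap > 500 nt between consecutive sorted positions starts a new
cluster; a tie at exactly 500 merges. The 500-nt separation is the standard
distance at which two TSS groups are considered to belong to distinct
promoters. Clustering is order-invariant, partitions its input, and cluster
count is non-increasing in the threshold (property-tested).

Cluster width (max − min member position) drives the shape call: sharp when
width ≤ 62 nt — the average scatter reported for focused promoters — else
broad. The cutoff is a configurable default, not a biological constant.
The TATA scan uses consensus TATAWAWR on the sense strand with the motif
start constrained to [−40, −20] relative to the cluster representative
(5′-most member); the leftmost hit is reported, and windows truncated by the
contig edge are scanned as-is. Both window and consensus are conventions and
are exposed as configuration. An `exonic` flag marks clusters whose
representative lies strictly inside an internal or coding exon *and* more
than 500 nt from every annotated transcript start; closer candidates are
considered scatter of that start's promoter. No CpG-island model is included.

## First-exon taxonomy

An alternative first exon is classified against the reference:

* **canonical** — starts within 62 nt of the reference first-exon start (the
  same TSS-scatter tolerance as promoter shape, so one promoter's scatter is
  one exon);
* **mutually_exclusive_first** — zero overlap with any reference exon and a
  donor that joins a downstream reference acceptor. Overlap by even 1 nt
  reclassifies the exon as an extension: that is the operative distinction
  between a genuinely alternative first exon and a 5′-extended constitutive
  exon;
* **five_prime_extension** — shares the 3′ (donor) boundary of reference exon
  N; labelled "NL";
* **intron_retaining_first** — overlaps two or more reference exons, i.e.
  runs uninterrupted through at least one intron. `retained_nt` counts all
  nucleotides of the first exon overlapping reference introns, including a
  partial overlap of the upstream intron when the exon starts inside it.

First exons that anchor nowhere are reported as `unresolvable` warnings
rather than forced into a class; transcripts whose 3′ structure is unknown
are treated as structurally incomplete, and no 3′ ends are inferred.

## Splice-event diffing

The diff aligns the two exon chains on the shared suffix: after the
first-exon call, comparison starts at the canonical first exon (acceptor
scatter suppressed), at the anchor acceptor for mutually exclusive first
exons, or just after the anchor exon for extensions and retaining first
exons. A two-pointer walk then assigns every boundary difference to exactly
one event:

* runs of reference exons absent between two alternative exons → one
  `skipped_exon` event per contiguous run (delta = −sum of exon lengths);
* a novel alternative exon replacing a single absent reference exon between
  the same flanks → `mutually_exclusive_pair` (delta = length difference);
* an alternative exon overlapping several reference exons →
  `intron_retention` with the bridged introns' total as delta and interior
  exons recorded as subsumed (retained reference exons count toward the mRNA
  but not toward delta, which is purely intronic);
* boundary shifts: acceptor-side differences are always `alt_acceptor`
  (signed; a ±3-nt shift is checked for a NAGNAG site); donor shifts into
  the exon are `alt_donor`; donor extensions into the intron are
  `cryptic_donor_utr` when they lie entirely 5′ of the CDS start (they change
  only the 5′-UTR) and partial `intron_retention` otherwise.

Events are emitted 5′→3′ and the engine asserts that deltas sum to the
spliced-length difference over the compared region; 3′-terminus differences
are not splice events and suspend that check with a warning.

NAGNAG detection tests the intron-terminal hexamer (the 6 nt ending one base
before an exon's first nucleotide) against NAGNAG. Nomenclature: the
*proximal* AG is the upstream AG, whose use yields the longer mRNA; the
*distal* AG the downstream one. The report header restates this.

Mutually exclusive pair detection across a transcript set groups overlapping
internal-exon variants (a donor-shifted variant of exon 9b is still exon 9b),
assigns each group its flanking reference exons, and pairs disjoint groups
that share flanks, appear in at least one transcript each, and never co-occur
in a transcript.

## Coding consequences

With a CDS annotation the ORF is translated directly; without one the policy
is first AUG to first in-frame stop, no Kozak scoring — matching how ORFs are
read off cloned cDNAs. For event consequences the alternative transcript is
translated from the reference start codon mapped through the coordinate map,
so UTR events provably leave the protein bit-identical (`silent_utr`).

In-frame events (delta ≡ 0 mod 3) are resolved by common-prefix/common-suffix
alignment of the two proteins: a codon-aligned excision is a pure
`inframe_deletion` of |delta|/3 residues; a non-codon-aligned cut leaves one
chimeric junction codon, reported as a substitution only when the translated
residue actually changes (a synonymous chimeric codon demotes the call to a
plain deletion). Deleted runs use leftmost placement in repeat context and
substitutions align at the right edge of the changed run, so a G,K,Y → D
change reads as deletion of G and K plus substitution Y→D. Positive in-frame
deltas are reported as `inframe_insertion` and equal-length exchanges (e.g.
mutually exclusive exon swaps) as substitution runs — natural extensions of
the deletion vocabulary needed for a total event→consequence function.

Frame-disrupting deltas are traced to the first downstream in-frame stop
(the PTC, in spliced coordinates of the alternative transcript); the isoform
is an NMD candidate when the PTC lies more than 50 nt upstream of the last
exon-exon junction. The 50-nt rule is the standard convention; the flag is
advisory and the distance configurable.

N-terminal truncation bookkeeping uses the longest common suffix:
`shared_suffix`, `unique_n = len(alt) − shared_suffix`, `missing_n =
len(ref) − shared_suffix`, so `len(alt) = len(ref) − missing_n + unique_n`
holds by construction (asserted on every call). A zero shared suffix is
flagged "unrelated C-termini" rather than refused.

## Synthetic loci

The generator builds a reference as uniform-random sequence shaped by
constraints, then derives each alternative transcript by interval surgery,
recording the expected first-exon call, event (kind, ordinals, delta), and
consequence as it goes. Key engineering choices:

* exon boundaries are phase 0 by construction (codon-aligned), except where a
  feature requires an off-phase donor (the −6-nt deletion-plus-substitution
  construct plants a `GGT AAA T | AC` junction so the chimeric codon reads
  Y→D exactly);
* every intron begins GT and ends AG, including the introns of alternative
  isoforms (donor dinucleotides are planted at each alternative cut site);
* confounders are scrubbed so planted truth is exact: no ATG substring in
  introns or untranslated sequence except planted start codons, no NAGNAG
  hexamer at non-planted acceptors, no TATA consensus inside any scanned
  promoter window except the planted box, and planted stop codons guarantee
  every frameshift construct reaches a PTC;
* TSS evidence is planted exactly at the declared offsets (a jitter option
  exists for property tests), and declared clusters must be > 500 nt apart so
  the declared grouping is the true partition;
* feature compatibility is validated before generation (exclusive claims on
  exons, introns, donors, acceptors, and on phase-0 boundaries), and the
  generator back-checks each planted consequence by direct translation before
  returning.

Defaults: 90–150-nt exons, 250–450-nt introns, CDS starting in exon 2 with a
60-nt 5′-UTR segment and 60-nt 3′-UTR — small enough that a full locus
generates in milliseconds, large enough that every feature class fits. The
`auts2a-like` preset scales the architecture to 19 exons with a long (1.2-kb)
untranslated first exon and the full feature inventory; test suites run on
~100 randomly drawn loci of 8–12 exons.

What the generator does **not** emulate: realistic base composition or codon
usage, CpG islands, expression levels, read noise, alignment artefacts,
assembly gaps, alternative polyadenylation, or 3′-end variation. Passing
tests therefore demonstrate the correctness of the structural logic — not
robustness to noisy real-world evidence, where truncated cDNAs and
misalignments produce 5′ ends this pipeline would dutifully classify.

## Numerical and degenerate-input choices

Thresholds (500-nt separation, 62-nt sharp width and canonical tolerance,
50-nt NMD distance, TATA window) are configuration keys logged in every
report. Clustering ties at the threshold merge. Empty evidence gives an empty
cluster table, a lone transcript an empty event table. Transcripts without an
AUG or in-frame stop are recorded as non-coding rather than failing.
Acceptors within 6 nt of the contig start cannot host a NAGNAG test and
return no site. Degenerate 1-based intervals (start = end) have length 1.

## Known limitations

* The diff assumes shared 3′ structure; transcripts ending early yield a
  warning and no tail events rather than a 3′-end taxonomy.
* Overlap between an exonic promoter's cluster and a neighbouring promoter is
  reported as two clusters; no attempt is made to decide whether they share
  regulatory elements.
* The NMD flag is a distance rule, not a decay model.
* Published isoform inventories occasionally contain internally inconsistent
  length arithmetic (e.g. a truncation triple off by a residue or two from an
  unstated junction effect); the pipeline reports what the sequences imply
  and does not special-case such pairs.
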