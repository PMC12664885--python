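# Methods

## The observation model

An EM-seq library is double stranded: after conversion and amplification a
sequenced fragment descends from either the original top strand or the
original bottom strand.  Aligned to the unconverted reference, top-strand
reads live in **CT space** (unmethylated C reads as T) and bottom-strand
reads in **GA space** (the complementary rule: unmethylated C on the bottom
strand appears as G→A on the top-strand coordinates).  All allele and
methylation logic derives from one primitive, `convert_base(base, space,
methylated)`, and its closure `observation_set(allele, space)`:

```
CT: obs(C) = {C,T},  obs(A)= {A}, obs(G) = {G}, obs(T) = {T}
GA: obs(G) = {G,A},  others singletons
```

At a biallelic site the observed base supports REF when it lies in
`obs(ref) \ obs(alt)`, ALT in the opposite difference, is AMBIGUOUS in the
intersection and OTHER (including N) outside the union.  Consequences worth
stating explicitly:

- C/T SNPs in CT space and G/A SNPs in GA space are *inherently*
  indistinguishable for reads in that space: an observed T may be a
  converted unmethylated C or a genuine T.  Such observations become
  AMBIGUOUS, never a guess.  Reads from the other space still resolve the
  site, so the information loss is roughly halved depth at those SNPs.
- Every genomic C is treated as possibly methylated, CpG context or not.
  This is deliberately conservative: EM-seq gives no per-site guarantee
  that a non-CpG cytosine is unmethylated, and the alternative (trusting
  non-CpG Cs to convert) would turn occasional non-CpG methylation into
  systematic allele miscalls.
- Insertions or deletions over a variant or CpG position yield no
  observation at all (pileup-style base lookup only).

Conversion-space assignment trusts a SAM tag (`XC:CT/GA`) when the aligner
provides one; otherwise it is inferred from the read's own mismatch
pattern: count reference-C-read-T and reference-G-read-A positions
(excluding known variants) and require both an absolute count (default 10)
and a dominance ratio (default 0.8).  Converted multi-kilobase reads carry
hundreds of conversions, so these thresholds fail only tiny or pathological
reads, which are excluded rather than guessed.

## CpG methylation calling

A CpG is keyed by the 0-based position of its top-strand C.  CT-space reads
vote through the base over the C (C methylated, T unmethylated), GA-space
reads through the base over the paired G at position+1 (G methylated, A
unmethylated); other bases are uninformative.  Votes from both strands are
destranded into one record, assuming symmetric CpG methylation
(hemimethylation is not modelled).  CpGs overlapping a known variant at
either position are dropped, because the variant breaks the observation
model there.  With conversion efficiency *e* < 1 the estimated rate has the
known under-conversion bias `truth + (1 − truth)(1 − e)`; the package
reports raw rates and leaves bias correction to the user, as extractors
conventionally do.

## Pseudo reads and phasing

For each primary alignment covering heterozygous SNPs, the restored allele
(`restore_base`) is written at each variant position and every other base
becomes N, preserving coordinates and CIGAR.  These pseudo reads are the
interface to phasing: exported as SAM they feed any external read-backed
phaser, and the phased VCF (with PS tags) can be read back for
haplotagging.  Only primary alignments participate, which keeps complex
structural variants — typically primary + supplementary combinations — out
of the phase signal.

The built-in phaser is a greedy spanning-forest heuristic, not a
reimplementation of an MEC solver: variants are nodes; for every variant
pair co-covered informatively by a read, cis and trans observations are
counted; edges are weighted |cis − trans| with orientation sign(cis −
trans); edges below `min_link = 2` are dropped (a single linking read is
unreliable at 1–2% base error, and a cis/trans tie carries no signal); a
maximum-weight spanning forest then orients each tree into one phased
block.  On small well-covered instances this agrees with exhaustive
minimum-error-correction phasing (tested against a brute-force oracle);
on adversarial instances MEC and the forest can differ, which is accepted —
the contribution here is the pseudo-read construction, and the external
phaser path preserves the exact published workflow.

Haplotagging is a majority vote over the phased alleles a read covers, with
a margin of at least one vote; ties and uncovered reads stay UNTAGGED.  A
read spanning several blocks is scored on the block where it covers most
sites, since cross-block haplotype labels are undefined.  When phased
blocks are short an optional mode additionally partitions reads at
singleton (unphased) het SNPs into per-site allele groups.  SNV
classification is genome-wide by default: a read supporting the somatic
allele anywhere is SNV+; one covering SNVs and supporting reference
everywhere is SNV−; reads with only ambiguous SNV observations are
unassigned (a per-locus mode exists for locus-restricted questions).
Switch error compares consecutive variant pairs phased in both test and
truth within single blocks, so it is invariant to global block flips; block
N50 is computed over block genomic spans.

## DMR calling

Inputs are per-CpG count tables per group.  Coverage floors follow assay
practice: ≥5 reads per CpG per group for sample-level comparisons, ≥3 for
allele-resolved ones (splitting reads by haplotype or SNV class roughly
halves depth).  Shared covered CpGs are segmented into runs broken at
inter-CpG gaps >300 bp; within a run the contiguous window of ≥10 CpGs is
selected greedily and removed, recursing on the flanks; all extracted
windows are tested with a two-sided Mann–Whitney U on the per-CpG rate
vectors (exact distribution when both sides have n < 8, asymptotic with tie
correction otherwise — per-CpG rates tie heavily at 0 and 1) and
Benjamini–Hochberg adjusted genome-wide; regions with q < 0.01 are
reported.

Window selection maximises |mean rate difference| · √n among windows whose
|mean difference| ≥ 0.1.  The √n factor (the shape of a standardised mean
difference) matters: the raw |mean| criterion is maximised by minimum-length
windows inside any sustained difference, shredding one long differential
region into several minimum-size calls, whereas the standardised score
extends the window to the full extent of the difference and stops when
background CpGs would dilute it.  Degenerate windows (both rate vectors
identical and constant) get p = 1 by convention and are never reported.

Merging unions overlapping or bookended intervals across per-sample DMR
lists and re-scores every sample on the union as the mean of per-CpG rates
passing the coverage floor; samples with no passing CpG are flagged not
measurable (NaN).  The filter cascade then applies, in order: a
measurable-in-all-samples requirement, an optional any-pair difference
threshold (max − min across sample columns), and arbitrary per-sample rules
(all listed columns ≥ or < a threshold; differences are taken as absolute
values by default, configurable).  TSS proximity is the gap between the
interval and the TSS point (0 if inside), strand-ignored because the
±window rule is symmetric; a TSS exactly at the window edge counts as
within.

## Capture QC

Duplicates share (chromosome, orientation, unclipped 5′ start); the
representative is the longest aligned span.  Start-only keying matches
common single-end behaviour; an end-aware mode with a 3′ tolerance exists
for libraries where coincidental start sharing at very deep coverage
over-merges.  Metrics over non-duplicate primary alignments, clipped bases
excluded:

- mean bait coverage = on-target aligned bases / target territory
- fold enrichment = (on-target aligned bases / total aligned bases) ÷
  (territory / genome size)
- overlap rate = fraction of mapped reads intersecting any target by ≥1 bp
  (reported both before and after deduplication, since conventions differ)
- CpG coverage fraction at thresholds, and read N50 (largest L such that
  reads ≥ L hold at least half of all bases).

## Demultiplexing

Each barcode and its reverse complement is searched as an approximate
substring (edit distance ≤1 by default for 8-mers) within 60 bp of both
read ends; per end the best hit wins (lowest edit distance, then nearest
the read end).  One detected barcode assigns the read; two hits naming
different samples are an index-hopping signature and the read is removed,
as is a read with no barcode.  The sheet loader enforces the unique-dual
design and warns when two barcodes are close enough (≤ 2·max_edit) to
collide.  A more permissive search (larger window or edit budget) is
monotone in barcode *detection* but not necessarily in assignment, because
extra detections can surface as unexpected pairs — that removal is the
point of unique dual indexing.  Barcodes are searched on raw read ends by
default (they sit inside the retained P5/P7 flanks); an adapter-anchored
mode is available via the adapter locator.  Chimeric reads are split at
internal sequencing-adapter copies ≥100 bp from either end; end hits trim;
fragments under 200 bp are dropped.

## The simulator

The generator emulates the targeted assay end to end on one synthetic
chromosome.  What it models: random background sequence at GC 0.41 with
CpG-island cores (GC-rich plus explicit CpG planting, giving >3× background
CpG density) centred in evenly spaced capture targets; phased het SNPs at
1/1,500 bp with uniform alternate alleles (optionally restricted to
conversion-distinguishable patterns); clonal somatic SNVs placed inside
the island cores at a configurable carrier fraction (VAF); a methylome
with hypomethylated islands (Beta(1,10)) and hypermethylated open sea
(Beta(10,1)) shared across samples and haplotypes, so that only planted
regions (allele-specific, between-sample, or SNV-linked, occupying one
island each) are truly differential; lognormal fragments with a 5 kb N50
(σ = 0.4, so the length-weighted median exp(μ + σ²) equals the N50);
capture as a 0.9 probability of drawing the fragment from a random target;
methylation drawn **per molecule per CpG**, so allele- and SNV-linked
patterns are coherent along each molecule as long reads require;
conversion at efficiency 0.995 with over-conversion 0.005; PCR duplicates
as second copies of the converted molecule with independent sequencing
errors (a planted rate d emits extra copies at d/(1−d), so the flagged
fraction is d); iid substitution/insertion/deletion errors at 1%/0.5%/0.5%;
and, in multiplex mode, P5/P7 flanks and 8+8 bp unique dual indexes passed
through the same error process, with random read orientation.

Reads are emitted against the untransformed reference with the conversion
space in a tag, so the whole downstream stack runs without an aligner.
Every read has exactly one truth record (sample, haplotype, SNV carrier
status, origin, duplicate link), and a running tally records the drawn
methylation state at every CpG a read covers informatively — the exact
counts the caller must reproduce on error-free input.

What it does not model, hence what passing tests do not show: alignment
errors and reference bias (truth alignments are used), basecaller error
profiles beyond iid indels/substitutions (no homopolymer structure), pore
signal, hemimethylation and non-CpG methylation, GC or probe-proximity
capture bias (off-target fragments are uniform), PCR chimeras, aneuploidy
and subclonal structure (one clonal carrier fraction), and FFPE
degradation.  Performance numbers from the simulator are therefore
best-case with respect to alignment and error structure, while being
honest about conversion ambiguity, coverage, and the statistics.

## Problem sizes and numerical choices

Simulations in the test suite run on 0.1–2 Mb genomes at 20–60×, chosen so
the full suite completes in well under an hour on one core while every
check retains hundreds to thousands of informative events; the acceptance
script uses a 5 Mb genome at 30× (≈33,000 reads) for phasing and 10,000
multiplexed reads for demultiplexing.  Seeds fix every draw; identical
config and seed give byte-identical outputs, which the tests assert.
Tie-breaks are deterministic everywhere (edge sort order in the phaser,
position preference in barcode hits, lexicographic read ids for duplicate
representatives).  BH adjustment is applied genome-wide across extracted
windows, matching single q-value-column semantics.  Mean bait coverage and
fold enrichment on empty inputs return zeros with a warning rather than
raising, since empty strata occur routinely in small runs.

## Known limitations

- The spanning-forest phaser is a heuristic; at very low coverage or high
  error it fragments blocks rather than risking switches (by design), and
  block lengths are bounded by read length and SNP density.
- SNV classification assumes clonal carriers; per-molecule mixtures of
  subclones will dilute SNV+/SNV− methylation contrasts.
- The DMR caller is a defined replacement for external segmentation tools
  with matching interface and thresholds, not a bit-for-bit re-creation of
  any of them; absolute q-values will differ from other callers even when
  the called regions agree.
- Demultiplexing tie-breaks between equal-edit hits can mis-pick an end
  hit; with unique dual indexes this surfaces as an unexpected pair
  (removed) rather than a cross-sample assignment.
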