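# Methods

## The problem

Archival FFPE tumour RNA is heavily fragmented (median fragment around
100 bp) and rich in intronic sequence, so fusion-transcript discovery cannot
rely on paired-end spanning evidence or deep junction coverage.  gFuse
detects chimeric transcripts from single-end 50 bp directional reads by
combining *split-read* evidence within single reads with *expression
discontinuity* across a patient cohort: a fusion that removes a gene's 5'
(or 3') half leaves a visible step in that gene's exon/intron expression
profile even in samples where no read happens to straddle the junction.

## Junction notation

A fusion junction is the directed pair of stranded genomic positions
`<strand><chrom>:<pos>-><strand><chrom>:<pos>`, e.g.
`+chr17:5250220->+chr17:11532734`.  The donor position is the **last** base of
the preserved donor side, the acceptor position the **first** base of the
preserved acceptor side; `+`/`-` give the transcription direction relative to
the top chromosome strand.  A *fusion event* is one junction observed in one
sample.

## Pipeline

1. **Filter and map.**  Reads are kept when at least 15 bases have quality
   ≥ Q20, and dropped when they match an abundant-sequence blacklist
   (rRNA-like, PhiX-like) with ≥ 45/50 bases.  Mapping uses a seed-and-extend
   aligner (exact k-mer seeds, k = 15; match +1, mismatch −1, flat splice
   penalty 3) able to detect a *distant splice* inside one read: two segments
   on different chromosomes, strands, in inverted order, or ≥ 1 Mb apart.
   Uniquely mapped reads feed per-sample **gene tables**: base counts over
   every exon and intron of the collapsed (union-of-exons per symbol) gene
   models.
2. **Retest.**  Every distant-spliced read is re-aligned favouring a single
   locus, allowing one gap of ≤ 1 bp.  If ≥ 44 of its 50 bases then match one
   locus the read was a pseudo-chimera and is discarded.
3. **Extract junctions.**  Reads with a mismatch within 5 bases of the
   junction (the 5 terminal aligned bases of either segment) or antisense to
   an annotated gene are removed; survivors are grouped by exact junction
   coordinates and annotated.  Junctions in pseudogenes, unannotated regions
   or ambiguous (multi-gene) loci are rejected; same-gene rearrangements and
   read-throughs (co-directional, transcription order, < 1 Mb, different
   genes) are eliminated; the rest are candidates (different chromosomes,
   different genes, opposite strands, or ≥ 1 Mb apart).
4. **Five-template sets.**  Candidates from all cohorts are pooled.  Per
   junction, five 100 bp templates are built, each two 50 bp flanks joined at
   a junction: fusion (donor-preserved + acceptor-preserved exonic), donor
   mRNA, acceptor mRNA, donor pre-mRNA and acceptor pre-mRNA (raw genomic
   flanks).  Exonic flanks are spliced sequence in transcription orientation;
   no fusion pre-mRNA exists because the DNA breakpoint is unknown.
   Candidates sharing a byte-identical template with another set are removed
   (both of them), as are candidates whose 300 bp donor/acceptor templates —
   mRNA or pre-mRNA — share an exact substring of ≥ 15 bp, or that lack
   50 bp of exonic sequence on a required side.  The homology check is an
   exact shared-15-mer test (equivalent to longest common substring ≥ 15):
   deterministic and, at these template sizes, stricter than a gapped
   aligner's hit at the same threshold.  A 300 bp set per junction is also
   exported for assay design.
5. **Remap.**  Per library, reads near any template flank (padded by the
   read length) plus all unmapped reads are re-aligned contiguously
   (splicing off) against the pooled template index.  A read supports a
   fusion only if it is uniquely best on the *fusion* template, overhangs the
   junction midpoint by ≥ 6 bases and has no mismatch inside the overhang.
   The floor of 6 keeps genuine junction reads that reach only ~10 bases
   into their acceptor while suppressing chance matches of a random 50-mer.
6. **Profile expression.**  Gene tables are normalised by DESeq-style
   median-of-ratios size factors.  For each profiled junction and sample the
   **Interrupt Ratio** is, per gene side,

       IR = mean over preserved-side features of c(f)/len(f)
            ───────────────────────────────────────────────
            mean over discarded-side features of c(f)/len(f)

   with `c(f) = max(count/size_factor, 5)` (a floor of 5 keeps ratios finite
   in shallow features) and with the intron immediately downstream of the
   donor splice site / immediately upstream of the acceptor splice site
   excluded, because the genomic breakpoint falls somewhere inside it.  This
   ratio-of-mean-length-normalised-coverages form is this package's
   definition; variants (e.g. ratios of raw feature counts) order samples
   almost identically for a fixed gene structure but are not interchangeable
   in absolute value.  Cohorts are profiled separately (block age and library
   quality differ between cohorts) although the template index is pooled.
   Samples are ranked by max(IR_donor, IR_acceptor) and flagged *interrupted*
   when that value reaches max(3 × cohort median, 2.0) — a package choice
   sized to flag the planted discontinuities while leaving fusion-free
   cohorts empty.
7. **Classify.**  Tier-1: ≥ 2 non-redundant junction reads (distinct
   (offset, sequence) pairs), regardless of expression.  Tier-2: exactly one
   read plus an interrupted pattern.  Tier-3: no reads, an interrupted
   pattern, and the same junction carrying Tier-1/2 (or externally confirmed)
   status in another sample.  Everything else is rejected; junctions shared
   by many samples with no read or expression evidence anywhere die here.
   Cases that in practice would invite a manual review are resolved by these
   deterministic rules alone.  Reading frame is predicted from
   per-transcript CDS phase arithmetic (donor coding bases through the
   junction mod 3 versus acceptor coding bases before the acceptor position
   mod 3), with `noncoding` when either side leaves every CDS and `unknown`
   when a position cannot be placed in any transcript's exons.

## The simulator

`gfuse.simulate` generates the study conditions end-to-end: a toy genome
(two chromosomes, 3.7 Mb, 20 multi-exon genes on both strands), a refGene
annotation, an abundant-sequence blacklist, per-sample FASTQ and a truth TSV.

* **Fragments** are log-normal with the median pinned at 100 bp (σ = 0.45, a
  free parameter — only the median is documented for the real protocol) and
  a 20 bp floor; fragments shorter than the 50 bp read are dropped, as
  adapter-trimmed short inserts would be.
* **Intronic fraction**: 65 % of transcript molecules are left unspliced,
  which puts the intronic base fraction of emitted reads near 0.6 — the
  hallmark of FFPE libraries this pipeline targets.
* **Reads** are the first 50 bases of a fragment on the sense strand
  (directional protocol; zero antisense reads), constant Q35 by default —
  quality-filter behaviour is tested with purpose-built low-quality reads,
  not the simulator default.
* **Fusions** splice a donor exon boundary to an acceptor exon boundary.
  Junction-spanning reads are planted explicitly at distinct offsets
  (≥ 20 bp on each side), so `junction_reads_target` is exact — required to
  exercise the ≥2 / =1 / =0 read tiers precisely.  Expression discontinuity
  is added as extra molecules of the donor-preserved and acceptor-preserved
  spliced segments with abundance `expression_fold ×` the acceptor's
  baseline mRNA level.
* **Microhomology removal**: with random sequence, roughly a quarter of
  junctions would carry ≥ 1 bp of flanking microhomology, making the
  coordinate ambiguous for *any* read-based caller.  Since the generator
  owns the genome, it edits the discarded-side genomic neighbour of a
  planted junction whenever it collides with the base across the junction.
  The fusion mRNA itself is never altered.
* Everything is deterministic given the seed; two builds are byte-identical.

What the simulator does **not** model: formalin adduct errors, PCR
duplicates, paired ends, sequence-composition bias, real rRNA sequence, or
alternative splicing.  Passing tests therefore demonstrate the pipeline's
logic and thresholds under clean FFPE-like geometry, not performance on the
error profile of real libraries.

## Numerical and design choices

* Internal coordinates are 1-based inclusive everywhere; refGene's 0-based
  half-open form is converted at parse time.
* Mapping uniqueness is strict: any tie in best score (including a second
  equally good locus pair for a split read) clears the unique flag.
  Microhomology shifts of the same locus pair are one placement; the split
  is canonicalised to the longest donor extension.
* Read-through is operationalised as co-directional, transcription-order,
  < 1 Mb, different genes; the distance deliberately mirrors the 1 Mb
  candidacy rule rather than introducing a second free parameter.
* Criterion (4)'s 1 Mb distance is measured junction-to-junction.
* Pseudogene flagging comes from a configurable id list, since refGene
  itself carries no pseudogene column; the default list is empty.
* The remap stage re-applies the Step-1 quality filter ("good quality" reads
  — assumed to mean the same rule) and requires ≥ 90 % matching bases for
  any template placement to count.
* Sizes used in tests and in `scripts/acceptance.py`: 12-sample cohorts at
  17 000 reads/sample (≈ 2 × 10⁵ reads) for recovery and specificity,
  8 samples at 12 000 reads for the rescue pathways — large enough that
  feature counts clear the floor of 5 in expressed genes, small enough to
  keep a full run in minutes on one CPU.

## Known limitations

* The toy aligner indexes a few megabases; real cohorts enter through SAM
  ingestion of an external split-read aligner's output (supplementary
  records; mismatch positions via the `XZ` tag written by this package's
  own SAM export, since plain SAM without MD tags cannot supply them).
* The IR definition is this package's own (above); absolute IR values depend on
  the intron/exon mix of each side and are not comparable across gene
  structures — only the within-cohort ranking is used.
* Tier-3's cross-sample anchor generalises a wet-lab-confirmed anchor to
  "Tier-1/2 elsewhere or a supplied confirmed-junction list"; no
  quantitative expression-similarity measure is applied beyond the
  interrupted flag at the shared junction.
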