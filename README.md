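# gFuse

Cohort-based fusion-transcript detection for short single-end RNA-seq from
degraded (FFPE) tumour RNA, with a synthetic FFPE cohort simulator.

## Why

RNA from formalin-fixed, paraffin-embedded tissue is fragmented to a median
of ~100 bp and carries a large intronic fraction, so fusion discovery from
50 bp single-end directional reads cannot lean on paired-end spanning
evidence.  gFuse combines two signals:

* **split reads** — single reads whose alignment breaks into two segments
  across a *distant splice* (different genes, chromosomes, strands, or
  ≥ 1 Mb apart), written as a directed junction
  `+chr17:5250220->+chr17:11532734` (donor position = last preserved donor
  base, acceptor position = first preserved acceptor base);
* **expression discontinuity** — a fusion leaves a step in the partner
  genes' exon/intron expression profile at the junction, quantified per
  sample by the Interrupt Ratio

  `IR = mean(preserved-side coverage) / mean(discarded-side coverage)`

  over length-normalised, library-size-normalised, floored feature counts,
  with the breakpoint-adjacent intron excluded.

Candidate junctions from all samples (and cohorts) are pooled into
*five-template sets* — fusion, donor mRNA, acceptor mRNA, donor pre-mRNA,
acceptor pre-mRNA, each 100 bp around a junction — against which every
library's near-junction and unmapped reads are re-mapped.  Events are then
tiered: **Tier-1** ≥ 2 non-redundant junction reads; **Tier-2** 1 read plus
an interrupted expression pattern; **Tier-3** no reads but an interrupted
pattern at a junction with Tier-1/2 evidence in another sample.  See
`docs/methods.md` for the full model and the design decisions.

## Worked example

Simulate the standard demonstration cohort — 12 samples, 50 bp directional
reads, ~60 % intronic bases, six implanted fusions (two inter-chromosomal,
two co-directional partners > 1 Mb apart, one opposite-strand pair, one
recurrent in two samples) — and run the pipeline on it:

```bash
gfuse simulate --seed 1 --out demo
gfuse run --fastq-dir demo --genome demo/genome.fa --refgene demo/refGene.txt \
          --blacklist demo/blacklist.fa --out demo/report
```

The run prints the per-step retention counts and the call summary:

```
reads_total     204000
reads_after_quality     204000
reads_after_abundance   193800
distant_reads   155
distant_reads_after_retest      101
junctions_grouped       15
junctions_candidates    6
junctions_after_dedupe  6
junctions_after_homology        6
junctions_with_read_support     6
events_called   7
junctions_called        6
called 7 fusion events (6 junctions) -> demo/report
```

Reading it: 204 000 reads survive the quality filter, 5 % are removed as
rRNA/PhiX-like contaminants, 155 reads look distant-spliced and 101 survive
the local-realignment retest.  They group into 15 exact junctions, of which
6 meet the candidacy criteria; none are lost to the duplicate-template or
homology filters, all 6 attract unique junction-spanning reads on remapping,
and 7 events are called — the 6 planted junctions, with the recurrent one
found in both of its carrier samples, every one Tier-1 at base-pair-exact
coordinates.  `demo/report/fusions.tsv` then holds one row per event, e.g.

```
junction                        donor_gene acceptor_gene sample tier   n_nonredundant_reads ir_donor ir_acceptor in_frame
-chr1:12228->-chr2:38117        GENE01     GENE14        S01    Tier-1 4                    3.7102   7.7243      in
+chr1:407375->+chr1:1850863     GENE03     GENE11        S03    Tier-1 4                    7.2035   4.7507      out
```

with the 300 bp assay-design templates in `assay_templates_300bp.fa` and the
full evidence grid (including rejected junction × sample pairs) in
`evidence.tsv`.  The same analysis is available in Python via
`gfuse.run_cohort(...)`, and per-stage subcommands (`gfuse map`,
`junctions`, `templates`, `remap`, `profile`, `classify`) exchange plain
SAM/TSV/FASTA so external alignments can be substituted.

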