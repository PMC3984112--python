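"""End-to-end orchestration of the fusion-detection pipeline.

Per-sample stage (sample-based strategy): quality/abundance filtering,
genome mapping with within-read splice detection, the local-realignment
retest of distant-spliced reads, and gene-table counting.  Cohort stage
(cohort-based strategy): junction grouping and annotation pooled over every
sample, five-template construction with duplicate/homology removal, template
remapping per library, expression profiling per cohort, and tier
classification across the whole cohort.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import align as al
from .align import (FeatureIndex, GeneTable, Read, SegmentAlignment, SeqIndex,
                    abundance_filter, count_features, load_fastq, map_read,
                    quality_filter, retest_distant_read)
from .classify_report import FusionCall, classify_cohort, predict_frame, write_report
from .genome_model import (GeneModel, Genome, Junction, collapse_by_symbol,
                           format_junction_string, parse_refgene)
from .junctions import (AnnotatedJunction, GeneSpanIndex, group_and_annotate,
                        is_candidate_fusion, junction_read_filter)
from .remap_profile import (ExpressionEvidence, TemplateHit, fusion_support_reads,
                            interrupt_ratio, nominate_interrupted,
                            remap_to_templates, select_reads_for_remap,
                            size_factors)
from .templates import (TemplateError, TemplateIndex, TemplateSet,
                        build_template_index, build_template_set,
                        dedupe_template_sets, homology_filter)

__all__ = ["SampleData", "PipelineResult", "process_sample", "run_cohort"]


@dataclass
class SampleData:
    """Everything the cohort stage needs from one library."""

    sample: str
    reads: dict[str, Read]
    alignments: dict[str, SegmentAlignment]
    read_intervals: dict[str, list[tuple[str, int, int]]]
    unmapped_ids: set[str]
    distant: list[SegmentAlignment]
    feature_counts: dict[str, int]
    aligned_bases: int
    n_total: int = 0
    n_after_quality: int = 0
    n_after_abundance: int = 0
    n_distant_raw: int = 0
    n_distant_retested: int = 0


def process_sample(sample: str, reads: list[Read], genome_index: SeqIndex,
                   blacklist_index: SeqIndex, feature_index: FeatureIndex
                   ) -> SampleData:
    """Run the sample-based stage on one library."""
    data = SampleData(sample, {}, {}, {}, set(), [], {}, 0)
    data.n_total = len(reads)
    kept: list[Read] = []
    for read in reads:
        if not quality_filter(read):
            continue
        data.n_after_quality += 1
        if not abundance_filter(read, blacklist_index):
            continue
        data.n_after_abundance += 1
        kept.append(read)
    unique_alignments: list[SegmentAlignment] = []
    for read in kept:
        data.reads[read.id] = read
        alns = map_read(read, genome_index)
        if not alns:
            data.unmapped_ids.add(read.id)
            continue
        aln = alns[0]
        data.alignments[read.id] = aln
        data.read_intervals[read.id] = [(s.chrom, s.gstart, s.gend) for s in aln.segments]
        if aln.unique:
            unique_alignments.append(aln)
        if aln.kind == "distant_spliced" and aln.unique:
            data.n_distant_raw += 1
            if retest_distant_read(read, genome_index):
                data.distant.append(aln)
    data.n_distant_retested = len(data.distant)
    data.feature_counts, data.aligned_bases = count_features(unique_alignments,
                                                             feature_index)
    return data


@dataclass
class PipelineResult:
    calls: list[FusionCall]
    junctions: list[AnnotatedJunction]
    candidates: list[AnnotatedJunction]
    sets100: dict[str, TemplateSet]
    sets300: dict[str, TemplateSet]
    gene_table: GeneTable
    size_factors_by_cohort: dict[str, pd.Series]
    expression: dict[str, dict[str, ExpressionEvidence]]
    support: dict[str, dict[str, list[TemplateHit]]]
    retention: dict[str, int]
    report_paths: dict[str, str] = field(default_factory=dict)

    def calls_by_tier(self, tier: int | str) -> list[FusionCall]:
        return [c for c in self.calls if c.tier == tier]


def run_cohort(genome: Genome, transcripts: list[GeneModel],
               fastqs: dict[str, str] | dict[str, list[Read]],
               blacklist: Genome | str, outdir: str | None = None,
               cohorts: dict[str, str] | None = None,
               confirmed_junctions: set[str] = frozenset(),
               genome_k: int = 15) -> PipelineResult:
    """Run the whole pipeline on a cohort.

    ``fastqs`` maps sample name to a FASTQ path (or directly to a read list);
    ``cohorts`` maps sample to cohort label (default: one cohort).  Returns a
    :class:`PipelineResult`; when ``outdir`` is given the report files are
    written there too.
    """
    collapsed = collapse_by_symbol(transcripts)
    spans = GeneSpanIndex(collapsed)
    findex = FeatureIndex(collapsed)
    tx_by_symbol: dict[str, list[GeneModel]] = {}
    for tx in transcripts:
        tx_by_symbol.setdefault(tx.symbol, []).append(tx)
    genome_index = SeqIndex(genome.sequences, k=genome_k)
    bl_genome = blacklist if isinstance(blacklist, Genome) else Genome.from_fasta(blacklist)
    blacklist_index = SeqIndex(bl_genome.sequences, k=12)

    samples = list(fastqs)
    cohorts = cohorts or {s: "cohort1" for s in samples}

    # ---- sample-based stage -------------------------------------------------
    sample_data: dict[str, SampleData] = {}
    table = GeneTable(findex.features)
    for sample in samples:
        src = fastqs[sample]
        reads = load_fastq(src) if isinstance(src, str) else list(src)
        data = process_sample(sample, reads, genome_index, blacklist_index, findex)
        sample_data[sample] = data
        table.add_sample(sample, data.feature_counts, data.aligned_bases)

    retention: dict[str, int] = {
        "reads_total": sum(d.n_total for d in sample_data.values()),
        "reads_after_quality": sum(d.n_after_quality for d in sample_data.values()),
        "reads_after_abundance": sum(d.n_after_abundance for d in sample_data.values()),
        "distant_reads": sum(d.n_distant_raw for d in sample_data.values()),
        "distant_reads_after_retest": sum(d.n_distant_retested for d in sample_data.values()),
    }

    # ---- junction extraction (pooled over samples and cohorts) --------------
    filtered_by_sample = {
        s: [a for a in d.distant if junction_read_filter(a, spans)]
        for s, d in sample_data.items()
    }
    junctions = group_and_annotate(filtered_by_sample, spans)
    retention["junctions_grouped"] = len(junctions)
    candidates = []
    for aj in junctions:
        ok, reason = is_candidate_fusion(aj, spans)
        if ok:
            candidates.append(aj)
        else:
            aj.rejection_reason = reason
    retention["junctions_candidates"] = len(candidates)

    def _finish(calls, sets100, sets300, support, expression, factors):
        tiers = [c for c in calls if c.tier != "rejected"]
        retention["events_called"] = len(tiers)
        retention["junctions_called"] = len({c.junction for c in tiers})
        result = PipelineResult(calls, junctions, candidates, sets100, sets300,
                                table, factors, expression, support, retention)
        if outdir:
            result.report_paths = write_report(calls, outdir, sets300, retention)
        return result

    # ---- five-template construction, dedupe, homology -----------------------
    sets100: dict[str, TemplateSet] = {}
    sets300: dict[str, TemplateSet] = {}
    aj_by_key: dict[str, AnnotatedJunction] = {}
    for aj in candidates:
        key = format_junction_string(aj.junction)
        try:
            s100 = build_template_set(aj.junction, genome, collapsed,
                                      aj.donor_gene, aj.acceptor_gene, width=100)
            s300 = build_template_set(aj.junction, genome, collapsed,
                                      aj.donor_gene, aj.acceptor_gene, width=300)
        except TemplateError:
            continue
        sets100[key] = s100
        sets300[key] = s300
        aj_by_key[key] = aj
    surviving = dedupe_template_sets(list(sets100.values()))
    retention["junctions_after_dedupe"] = len(surviving)
    kept = []
    for ts in surviving:
        keep, _ = homology_filter(sets300[ts.key], ts)
        if keep:
            kept.append(ts)
    retention["junctions_after_homology"] = len(kept)
    sets100 = {ts.key: ts for ts in kept}
    sets300 = {k: v for k, v in sets300.items() if k in sets100}
    if not sets100:
        for k in ("junctions_with_read_support",):
            retention[k] = 0
        return _finish([], sets100, sets300, {}, {}, {})

    index = build_template_index(list(sets100.values()))
    all_blocks = [b for ts in sets100.values() for b in ts.flank_blocks]

    # ---- template remapping per library -------------------------------------
    support: dict[str, dict[str, list[TemplateHit]]] = {}
    hits_by_junction_sample: dict[tuple[str, str], list[TemplateHit]] = {}
    for sample, data in sample_data.items():
        selected = select_reads_for_remap(data.read_intervals, data.unmapped_ids,
                                          all_blocks)
        reads = [data.reads[rid] for rid in sorted(selected) if rid in data.reads]
        hits = remap_to_templates(reads, index, sample)
        for h in hits:
            hits_by_junction_sample.setdefault((h.junction, sample), []).append(h)
    for (jkey, sample), hits in hits_by_junction_sample.items():
        sup = fusion_support_reads(hits)
        if sup:
            support.setdefault(jkey, {})[sample] = sup
    supported = sorted(support)
    retention["junctions_with_read_support"] = len(supported)
    if not supported:
        return _finish([], sets100, sets300, support, {}, {})

    # ---- expression profiling, separately per cohort ------------------------
    cohort_samples: dict[str, list[str]] = {}
    for s in samples:
        cohort_samples.setdefault(cohorts[s], []).append(s)
    factors_by_cohort: dict[str, pd.Series] = {}
    for cname, members in cohort_samples.items():
        sub = table.df[members]
        factors_by_cohort[cname] = size_factors(sub)
    expression: dict[str, dict[str, ExpressionEvidence]] = {}
    for jkey in supported:
        aj = aj_by_key[jkey]
        gd = collapsed[aj.donor_gene]
        ga = collapsed[aj.acceptor_gene]
        merged: dict[str, ExpressionEvidence] = {}
        for cname, members in cohort_samples.items():
            factors = factors_by_cohort[cname]
            irs = {s: interrupt_ratio(aj.junction, gd, ga, table, s, factors)
                   for s in members}
            merged.update(nominate_interrupted(irs, jkey))
        expression[jkey] = merged

    # ---- tier classification and frame prediction ---------------------------
    gene_pair = {j: (aj_by_key[j].donor_gene, aj_by_key[j].acceptor_gene)
                 for j in supported}
    calls = classify_cohort({j: support.get(j, {}) for j in supported},
                            expression, gene_pair, samples,
                            set(confirmed_junctions))
    frame_cache: dict[str, str] = {}
    for call in calls:
        if call.junction not in frame_cache:
            aj = aj_by_key[call.junction]
            # frame prediction uses the per-transcript models, not the
            # collapsed per-symbol union
            donor_tx = tx_by_symbol.get(aj.donor_gene.split("__")[0], [])
            acceptor_tx = tx_by_symbol.get(aj.acceptor_gene.split("__")[0], [])
            frame_cache[call.junction] = predict_frame(aj.junction, donor_tx,
                                                       acceptor_tx)
        call.in_frame = frame_cache[call.junction]
    return _finish(calls, sets100, sets300, support, expression, factors_by_cohort)


def run_from_paths(genome_fasta: str, refgene: str, fastq_dir: str,
                   blacklist_fasta: str, outdir: str,
                   cohorts: dict[str, str] | None = None,
                   confirmed_junctions: set[str] = frozenset(),
                   pseudogene_ids: tuple[str, ...] = ()) -> PipelineResult:
    """File-level convenience entry point (one FASTQ per sample in
    ``fastq_dir``, sample name = file stem)."""
    genome = Genome.from_fasta(genome_fasta)
    transcripts = parse_refgene(refgene, pseudogene_ids)
    fastqs = {}
    for fn in sorted(os.listdir(fastq_dir)):
        if fn.endswith((".fastq", ".fq")):
            fastqs[fn.rsplit(".", 1)[0]] = os.path.join(fastq_dir, fn)
    if not fastqs:
        raise FileNotFoundError(f"no FASTQ files in {fastq_dir}")
    return run_cohort(genome, transcripts, fastqs, blacklist_fasta, outdir,
                      cohorts, confirmed_junctions)
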