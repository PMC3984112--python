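"""Turning surviving distant-spliced reads into candidate fusion junctions.

Reads that still look distant-spliced after the local-realignment retest are
screened (junction-proximal mismatches, antisense placements), grouped by
their exact (donor, acceptor) position pair, annotated against the collapsed
per-symbol gene models, and finally tested against the candidacy criteria:
different chromosomes, different genes, opposite strands, or ≥ 1 Mb apart on
one chromosome — with same-gene rearrangements and transcriptional
read-throughs removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .align import SegmentAlignment, junction_of
from .genome_model import GeneModel, GenomePosition, Junction

__all__ = [
    "AnnotatedJunction",
    "GeneSpanIndex",
    "junction_read_filter",
    "group_and_annotate",
    "is_candidate_fusion",
]

JUNCTION_MISMATCH_WINDOW = 5  # terminal aligned bases of each segment, inclusive
MAX_READ_THROUGH_DISTANCE = 1_000_000


class GeneSpanIndex:
    """chrom → interval tree over gene (tx span) extents of collapsed models."""

    def __init__(self, gene_models: dict[str, GeneModel]):
        self.genes = gene_models
        self._trees: dict[str, IntervalTree] = {}
        for sym, g in gene_models.items():
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end + 1, sym)

    def overlapping(self, chrom: str, start: int, end: int | None = None) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        end = start if end is None else end
        return sorted(iv.data for iv in tree.overlap(start, end + 1))


@dataclass
class AnnotatedJunction:
    junction: Junction
    donor_gene: str | None
    acceptor_gene: str | None
    supporting_read_ids: set[str] = field(default_factory=set)
    # read ids broken out per sample (cohort bookkeeping)
    reads_by_sample: dict[str, set[str]] = field(default_factory=dict)
    rejection_reason: str | None = None


def junction_read_filter(aln: SegmentAlignment, spans: GeneSpanIndex) -> bool:
    """Keep (True) a retested distant-spliced read unless it has a mismatch
    within 5 bases of the junction on either segment, or either segment lies
    antisense to an annotated gene it overlaps.

    The 5 bp window counts the 5 terminal aligned bases of each segment
    adjacent to the junction, inclusive.  A segment overlapping no gene is not
    antisense (the unannotated case is handled at annotation time).
    """
    s1, s2 = aln.segments
    for q in s1.mismatches:
        if s1.qend - q < JUNCTION_MISMATCH_WINDOW:
            return False
    for q in s2.mismatches:
        if q - s2.qstart < JUNCTION_MISMATCH_WINDOW:
            return False
    for seg in (s1, s2):
        overlapping = spans.overlapping(seg.chrom, seg.gstart, seg.gend)
        if overlapping and all(spans.genes[sym].strand != seg.strand
                               for sym in overlapping):
            return False
    return True


def _annotate_side(pos: GenomePosition, spans: GeneSpanIndex
                   ) -> tuple[str | None, str | None]:
    """(gene symbol, rejection reason) for one junction end.  Only genes on
    the read's (sense) strand are eligible."""
    hits = [sym for sym in spans.overlapping(pos.chrom, pos.pos)
            if spans.genes[sym].strand == pos.strand]
    if not hits:
        return None, "unannotated"
    if any(spans.genes[sym].is_pseudogene for sym in hits):
        return None, "pseudogene"
    if len(hits) > 1:
        return None, "ambiguous"
    return hits[0], None


def group_and_annotate(alignments_by_sample: dict[str, list[SegmentAlignment]],
                       spans: GeneSpanIndex) -> list[AnnotatedJunction]:
    """Group filtered distant-spliced reads by exact junction coordinates and
    annotate each junction end to a collapsed gene model.

    Rejection reasons: ``pseudogene`` (either end in a flagged pseudogene),
    ``unannotated`` (either end outside every gene), ``ambiguous`` (either end
    inside more than one same-strand gene).  Grouping is a partition: every
    kept read lands in exactly one junction.
    """
    grouped: dict[Junction, AnnotatedJunction] = {}
    for sample, alns in alignments_by_sample.items():
        for aln in alns:
            dchrom, dpos, dstrand, achrom, apos, astrand = junction_of(aln)
            j = Junction(GenomePosition(dchrom, dpos, dstrand),
                         GenomePosition(achrom, apos, astrand))
            aj = grouped.get(j)
            if aj is None:
                dg, dreason = _annotate_side(j.donor, spans)
                ag, areason = _annotate_side(j.acceptor, spans)
                # pseudogene outranks unannotated outranks ambiguous
                reasons = [r for r in (dreason, areason) if r]
                reason = None
                for r in ("pseudogene", "unannotated", "ambiguous"):
                    if r in reasons:
                        reason = r
                        break
                aj = AnnotatedJunction(j, dg, ag, rejection_reason=reason)
                grouped[j] = aj
            aj.supporting_read_ids.add(aln.read_id)
            aj.reads_by_sample.setdefault(sample, set()).add(aln.read_id)
    return sorted(grouped.values(), key=lambda a: str(a.junction))


def is_candidate_fusion(aj: AnnotatedJunction, spans: GeneSpanIndex
                        ) -> tuple[bool, str | None]:
    """Candidacy verdict for an annotated junction.

    True iff the junction is neither within one gene nor a transcriptional
    read-through and at least one holds: (1) different chromosomes,
    (2) different gene symbols, (3) opposite strands on one chromosome,
    (4) ≥ 1 Mb apart on one chromosome.  A read-through is co-directional,
    in transcription order, between different genes, closer than 1 Mb.
    """
    if aj.rejection_reason is not None:
        return False, aj.rejection_reason
    d, a = aj.junction.donor, aj.junction.acceptor
    if aj.donor_gene == aj.acceptor_gene:
        return False, "same_gene"
    same_chrom = d.chrom == a.chrom
    distance = abs(d.pos - a.pos) if same_chrom else None
    if same_chrom and d.strand == a.strand and distance < MAX_READ_THROUGH_DISTANCE:
        downstream = a.pos > d.pos if d.strand == "+" else a.pos < d.pos
        if downstream:
            return False, "read_through"
    if not same_chrom:
        return True, None
    if aj.donor_gene != aj.acceptor_gene:
        return True, None
    if d.strand != a.strand:
        return True, None
    if distance >= 1_000_000:
        return True, None
    return False, "no_criterion"
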