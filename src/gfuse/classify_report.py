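"""Evidence integration: tier classification, reading-frame prediction and
final reports.

Tiers encode the strength of evidence for a fusion event (one junction in one
sample):

* **Tier-1** — ≥ 2 non-redundant junction-spanning reads, regardless of the
  expression profile;
* **Tier-2** — exactly 1 non-redundant read plus an interrupted expression
  pattern;
* **Tier-3** — no read at all, but an interrupted pattern at a junction that
  carries Tier-1/Tier-2 (or externally confirmed) evidence in another sample;
* everything else is rejected.

Non-redundancy collapses byte-identical reads at the same template offset —
PCR/optical duplicates of one molecule count once.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .genome_model import GeneModel, Junction, genomic_to_transcript, parse_junction_string
from .remap_profile import ExpressionEvidence, TemplateHit
from .templates import TemplateSet, write_templates_fasta

__all__ = [
    "FusionCall",
    "count_nonredundant",
    "classify_cohort",
    "predict_frame",
    "write_report",
]


@dataclass
class FusionCall:
    junction: str
    sample: str
    tier: int | str             # 1 | 2 | 3 | "rejected"
    donor_gene: str
    acceptor_gene: str
    n_nonredundant_reads: int
    interrupted: bool
    ir_donor: float | None
    ir_acceptor: float | None
    in_frame: str = "unknown"   # in | out | noncoding | unknown
    cross_sample_support: bool = False
    dominant: bool = True       # most-read junction among same-gene-pair calls


def count_nonredundant(support: list[TemplateHit]) -> int:
    """Distinct (template offset, read sequence) pairs among supporting reads."""
    return len({(h.offset, h.read_seq) for h in support})


def classify_cohort(
    support_by_junction: dict[str, dict[str, list[TemplateHit]]],
    expression_by_junction: dict[str, dict[str, ExpressionEvidence]],
    gene_pair: dict[str, tuple[str, str]],
    samples: list[str],
    confirmed_junctions: set[str] = frozenset(),
) -> list[FusionCall]:
    """Assign a tier to every (junction, sample) pair of the cohort.

    Two passes: read-based Tier-1/Tier-2 first, then Tier-3 rescue for
    samples whose only evidence is the expression pattern, anchored on a
    junction holding Tier-1/2 (or externally confirmed) status elsewhere.
    """
    calls: list[FusionCall] = []
    provisional: dict[tuple[str, str], FusionCall] = {}
    for jstr in support_by_junction:
        dg, ag = gene_pair[jstr]
        expr = expression_by_junction.get(jstr, {})
        for sample in samples:
            support = support_by_junction[jstr].get(sample, [])
            n = count_nonredundant(support)
            ev = expr.get(sample)
            interrupted = bool(ev and ev.interrupted)
            if n >= 2:
                tier: int | str = 1
            elif n == 1 and interrupted:
                tier = 2
            else:
                tier = "pending"
            provisional[(jstr, sample)] = FusionCall(
                junction=jstr, sample=sample, tier=tier, donor_gene=dg,
                acceptor_gene=ag, n_nonredundant_reads=n, interrupted=interrupted,
                ir_donor=ev.ir_donor if ev else None,
                ir_acceptor=ev.ir_acceptor if ev else None)
    for (jstr, sample), call in provisional.items():
        anchored = jstr in confirmed_junctions or any(
            other.tier in (1, 2)
            for (j2, s2), other in provisional.items()
            if j2 == jstr and s2 != sample)
        call.cross_sample_support = anchored
        if call.tier == "pending":
            if call.n_nonredundant_reads == 0 and call.interrupted and anchored:
                call.tier = 3
            else:
                call.tier = "rejected"
        calls.append(call)

    # one gene pair can yield several junctions in a sample; flag the
    # best-supported one as dominant
    by_pair: dict[tuple[str, str, str], list[FusionCall]] = {}
    for c in calls:
        by_pair.setdefault((c.donor_gene, c.acceptor_gene, c.sample), []).append(c)
    for group in by_pair.values():
        best = max(group, key=lambda c: c.n_nonredundant_reads)
        for c in group:
            c.dominant = c is best
    return calls


def predict_frame(junction: Junction, donor_transcripts: list[GeneModel],
                  acceptor_transcripts: list[GeneModel]) -> str:
    """Reading-frame status of the chimeric transcript.

    Uses per-transcript CDS bounds: the donor phase is the number of coding
    bases up to and including the junction mod 3, the acceptor phase the
    number of coding bases strictly 5' of the acceptor position mod 3;
    ``in`` iff the phases agree and both positions lie inside a CDS,
    ``noncoding`` if either side falls outside every CDS, ``unknown`` if a
    junction position cannot be placed in any transcript's exons.
    """
    def _phase(transcripts: list[GeneModel], pos: int, donor_side: bool
               ) -> tuple[str, int | None]:
        placed = False
        for tx in transcripts:
            t = genomic_to_transcript(tx, pos)
            if t is None:
                continue
            placed = True
            if not tx.coding:
                continue
            if tx.strand == "+":
                c0 = genomic_to_transcript(tx, tx.cds_start)
                c1 = genomic_to_transcript(tx, tx.cds_end)
            else:
                c0 = genomic_to_transcript(tx, tx.cds_end)
                c1 = genomic_to_transcript(tx, tx.cds_start)
            if c0 is None or c1 is None or not (c0 <= t <= c1):
                continue
            n = (t - c0 + 1) if donor_side else (t - c0)
            return "coding", n % 3
        return ("noncoding", None) if placed else ("unplaced", None)

    d_status, d_phase = _phase(donor_transcripts, junction.donor.pos, True)
    a_status, a_phase = _phase(acceptor_transcripts, junction.acceptor.pos, False)
    if "unplaced" in (d_status, a_status):
        return "unknown"
    if "noncoding" in (d_status, a_status):
        return "noncoding"
    return "in" if d_phase == a_phase else "out"


def write_report(calls: list[FusionCall], outdir: str,
                 template_sets_300: dict[str, TemplateSet] | None = None,
                 retention: dict[str, int] | None = None) -> dict[str, str]:
    """Emit the final fusion table, the 300 bp assay-design FASTA for every
    reported junction, and a per-step retention summary.  Only Tier-1/2/3
    events appear in the fusion table; the full evidence grid (including
    rejected pairs) goes to a companion file."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.4f}"

    header = ("junction\tdonor_gene\tacceptor_gene\tsample\ttier\t"
              "n_nonredundant_reads\tir_donor\tir_acceptor\tin_frame\tdominant\n")
    fusion_tsv = os.path.join(outdir, "fusions.tsv")
    with open(fusion_tsv, "w") as fh:
        fh.write(header)
        for c in sorted(calls, key=lambda c: (str(c.tier), c.junction, c.sample)):
            if c.tier == "rejected":
                continue
            fh.write(f"{c.junction}\t{c.donor_gene}\t{c.acceptor_gene}\t{c.sample}"
                     f"\tTier-{c.tier}\t{c.n_nonredundant_reads}\t{_fmt(c.ir_donor)}"
                     f"\t{_fmt(c.ir_acceptor)}\t{c.in_frame}\t{int(c.dominant)}\n")
    paths["fusions"] = fusion_tsv

    evidence_tsv = os.path.join(outdir, "evidence.tsv")
    with open(evidence_tsv, "w") as fh:
        fh.write(header)
        for c in sorted(calls, key=lambda c: (c.junction, c.sample)):
            fh.write(f"{c.junction}\t{c.donor_gene}\t{c.acceptor_gene}\t{c.sample}"
                     f"\t{c.tier}\t{c.n_nonredundant_reads}\t{_fmt(c.ir_donor)}"
                     f"\t{_fmt(c.ir_acceptor)}\t{c.in_frame}\t{int(c.dominant)}\n")
    paths["evidence"] = evidence_tsv

    if template_sets_300:
        reported = {c.junction for c in calls if c.tier != "rejected"}
        sets = [ts for key, ts in template_sets_300.items() if key in reported]
        assay_fa = os.path.join(outdir, "assay_templates_300bp.fa")
        write_templates_fasta(sets, assay_fa)
        paths["assay_fasta"] = assay_fa

    if retention is not None:
        summary = os.path.join(outdir, "run_summary.tsv")
        with open(summary, "w") as fh:
            fh.write("step\tcount\n")
            for step, count in retention.items():
                fh.write(f"{step}\t{count}\n")
        paths["summary"] = summary
    return paths
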