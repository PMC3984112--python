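"""Five-template sets per candidate junction and the pooled template index.

For each candidate fusion junction five width-100 (and, for assay design,
width-300) sequences are built, each two half-width flanks joined at a
junction:

* ``fusion_t``        donor-preserved exonic + acceptor-preserved exonic;
* ``donor_t``         donor-preserved + donor-discarded exonic (wild-type donor mRNA);
* ``acceptor_t``      acceptor-discarded + acceptor-preserved exonic (wild-type acceptor mRNA);
* ``donor_pre_t``     contiguous genomic sequence across the donor splice site;
* ``acceptor_pre_t``  contiguous genomic sequence across the acceptor splice site.

Exonic flanks are spliced transcript sequence written 5'→3' in the
transcription direction of their source gene; the DNA breakpoint being
unknown, no fusion pre-mRNA template exists.  Candidates whose templates
collide across sets (duplicated gene copies) or whose donor/acceptor templates
share a ≥15 bp exact substring (homologous partners) are removed before the
surviving 100 bp sets are pooled into one searchable index.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import SeqIndex
from .genome_model import (
    GeneModel,
    Genome,
    Junction,
    format_junction_string,
    genomic_to_transcript,
    spliced_sequence,
    transcript_blocks,
)

__all__ = [
    "TemplateSet",
    "TemplateIndex",
    "TemplateError",
    "ROLES",
    "build_template_set",
    "dedupe_template_sets",
    "homology_filter",
    "build_template_index",
    "shares_substring",
    "write_templates_fasta",
]

ROLES = ("fusion", "donor", "acceptor", "donor_pre", "acceptor_pre")
HOMOLOGY_MIN_SHARED = 15  # "more than 14 bp" of exact identity


class TemplateError(ValueError):
    """The junction cannot be placed in its annotated gene's exons."""


@dataclass
class TemplateSet:
    junction: Junction
    donor_gene: str
    acceptor_gene: str
    width: int
    fusion_t: str
    donor_t: str
    acceptor_t: str
    donor_pre_t: str
    acceptor_pre_t: str
    exonic_flank_ok: bool
    # genomic intervals of every flank, (chrom, start, end) — used to pick the
    # reads worth re-mapping
    flank_blocks: list[tuple[int, int, str]]

    def templates(self) -> dict[str, str]:
        return {
            "fusion": self.fusion_t,
            "donor": self.donor_t,
            "acceptor": self.acceptor_t,
            "donor_pre": self.donor_pre_t,
            "acceptor_pre": self.acceptor_pre_t,
        }

    @property
    def key(self) -> str:
        return format_junction_string(self.junction)


def _pad(seq: str, n: int, side: str) -> str:
    """Pad to length n with N on the given ('left'/'right') outer side."""
    if len(seq) >= n:
        return seq
    fill = "N" * (n - len(seq))
    return fill + seq if side == "left" else seq + fill


def _genomic_flank(genome: Genome, chrom: str, start: int, end: int, strand: str) -> str:
    """Strand-oriented genomic fetch, N-padded where the span leaves the
    chromosome."""
    clen = genome.length(chrom)
    lo, hi = max(start, 1), min(end, clen)
    if lo > hi:
        return "N" * (end - start + 1)
    seq = genome.fetch(chrom, lo, hi, strand)
    left = lo - start
    right = end - hi
    if strand == "-":
        left, right = right, left
    return "N" * left + seq + "N" * right


def build_template_set(junction: Junction, genome: Genome,
                       gene_models: dict[str, GeneModel],
                       donor_gene: str, acceptor_gene: str,
                       width: int = 100) -> TemplateSet:
    if width % 2 != 0:
        raise ValueError("template width must be even")
    h = width // 2
    gd = gene_models[donor_gene]
    ga = gene_models[acceptor_gene]
    t_d = genomic_to_transcript(gd, junction.donor.pos)
    t_a = genomic_to_transcript(ga, junction.acceptor.pos)
    if t_d is None:
        raise TemplateError(f"donor position {junction.donor} is not exonic in {donor_gene}")
    if t_a is None:
        raise TemplateError(f"acceptor position {junction.acceptor} is not exonic in {acceptor_gene}")
    sd = spliced_sequence(genome, gd)
    sa = spliced_sequence(genome, ga)
    don_pres = sd[max(t_d - h, 0): t_d]
    don_disc = sd[t_d: t_d + h]
    acc_pres = sa[t_a - 1: t_a - 1 + h]
    acc_disc = sa[max(t_a - 1 - h, 0): t_a - 1]
    flank_ok = all(len(x) == h for x in (don_pres, don_disc, acc_pres, acc_disc))

    blocks: list[tuple[int, int, str]] = []
    for g, lo, hi in ((gd, t_d - len(don_pres) + 1, t_d + len(don_disc)),
                      (ga, t_a - len(acc_disc), t_a + len(acc_pres) - 1)):
        for s, e in transcript_blocks(g, max(lo, 1), hi):
            blocks.append((s, e, g.chrom))

    dp, ds = junction.donor.pos, junction.donor.strand
    ap, as_ = junction.acceptor.pos, junction.acceptor.strand
    if ds == "+":
        donor_pre = (_genomic_flank(genome, gd.chrom, dp - h + 1, dp, "+")
                     + _genomic_flank(genome, gd.chrom, dp + 1, dp + h, "+"))
        blocks.append((max(dp - h + 1, 1), dp + h, gd.chrom))
    else:
        donor_pre = (_genomic_flank(genome, gd.chrom, dp, dp + h - 1, "-")
                     + _genomic_flank(genome, gd.chrom, dp - h, dp - 1, "-"))
        blocks.append((max(dp - h, 1), dp + h - 1, gd.chrom))
    if as_ == "+":
        acceptor_pre = (_genomic_flank(genome, ga.chrom, ap - h, ap - 1, "+")
                        + _genomic_flank(genome, ga.chrom, ap, ap + h - 1, "+"))
        blocks.append((max(ap - h, 1), ap + h - 1, ga.chrom))
    else:
        acceptor_pre = (_genomic_flank(genome, ga.chrom, ap + 1, ap + h, "-")
                        + _genomic_flank(genome, ga.chrom, ap - h + 1, ap, "-"))
        blocks.append((max(ap - h + 1, 1), ap + h, ga.chrom))

    return TemplateSet(
        junction=junction,
        donor_gene=donor_gene,
        acceptor_gene=acceptor_gene,
        width=width,
        fusion_t=_pad(don_pres, h, "left") + _pad(acc_pres, h, "right"),
        donor_t=_pad(don_pres, h, "left") + _pad(don_disc, h, "right"),
        acceptor_t=_pad(acc_disc, h, "left") + _pad(acc_pres, h, "right"),
        donor_pre_t=donor_pre,
        acceptor_pre_t=acceptor_pre,
        exonic_flank_ok=flank_ok,
        flank_blocks=blocks,
    )


def dedupe_template_sets(sets: list[TemplateSet]) -> list[TemplateSet]:
    """Drop every candidate any of whose five templates is byte-identical to a
    template of a *different* set (duplicate templates within one set — e.g. a
    single-exon gene whose mRNA and pre-mRNA coincide — are fine)."""
    owners: dict[str, set[int]] = {}
    for i, ts in enumerate(sets):
        for seq in set(ts.templates().values()):
            owners.setdefault(seq, set()).add(i)
    doomed = {i for ids in owners.values() if len(ids) > 1 for i in ids}
    return [ts for i, ts in enumerate(sets) if i not in doomed]


def shares_substring(a: str, b: str, n: int = HOMOLOGY_MIN_SHARED) -> bool:
    """True iff a and b share an exact common substring of length ≥ n
    (N-containing windows never count)."""
    kmers = {a[i: i + n] for i in range(len(a) - n + 1)}
    kmers = {k for k in kmers if "N" not in k}
    return any(b[i: i + n] in kmers for i in range(len(b) - n + 1)
               if "N" not in b[i: i + n])


def homology_filter(set300: TemplateSet, set100: TemplateSet
                    ) -> tuple[bool, str | None]:
    """(keep, reason) for one candidate, judged on its 300 bp set.

    Removed when the donor and acceptor mRNA templates share ≥ 15 bp of exact
    sequence, when the two pre-mRNA templates do, or when the 100 bp set lacks
    a full 50 bp exonic flank on any required side.
    """
    if not set100.exonic_flank_ok:
        return False, "short_exonic_flank"
    if shares_substring(set300.donor_t, set300.acceptor_t):
        return False, "donor_acceptor_homology"
    if shares_substring(set300.donor_pre_t, set300.acceptor_pre_t):
        return False, "pre_mrna_homology"
    return True, None


class TemplateIndex:
    """Searchable index over the pooled 100 bp templates of all surviving
    candidate sets; each template is tagged (junction, role)."""

    def __init__(self, sets: list[TemplateSet], k: int = 12):
        self.sets = {ts.key: ts for ts in sets}
        self.width = sets[0].width if sets else 100
        seqs: dict[str, str] = {}
        self.tags: dict[str, tuple[str, str]] = {}
        for ts in sets:
            for role, seq in ts.templates().items():
                name = f"{ts.key}|{role}"
                seqs[name] = seq
                self.tags[name] = (ts.key, role)
        self.seq_index = SeqIndex(seqs, k=k)

    def __len__(self) -> int:
        return len(self.tags)


def build_template_index(sets: list[TemplateSet], k: int = 12) -> TemplateIndex:
    if not sets:
        raise ValueError("no surviving template sets to index")
    return TemplateIndex(sets, k=k)


def write_templates_fasta(sets: list[TemplateSet], path: str) -> None:
    with open(path, "w") as fh:
        for ts in sets:
            for role, seq in ts.templates().items():
                fh.write(f">{ts.key}|{role} width={ts.width} "
                         f"donor={ts.donor_gene} acceptor={ts.acceptor_gene}\n{seq}\n")
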