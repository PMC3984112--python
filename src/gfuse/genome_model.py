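"""Genomic coordinate system, gene annotation and the fusion-junction notation.

All internal coordinates are 1-based inclusive on the top (forward) strand of
the chromosome; UCSC refGene's 0-based half-open coordinates are converted at
parse time.  A fusion junction is a directed pair of stranded positions written
``+chr17:5250220->+chr17:11532734``: the donor position is the LAST base of the
preserved donor side, the acceptor position the FIRST base of the preserved
acceptor side, and ``+``/``-`` give the transcription direction relative to the
top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomePosition",
    "Junction",
    "GeneModel",
    "Feature",
    "Genome",
    "parse_junction_string",
    "format_junction_string",
    "parse_refgene",
    "write_refgene",
    "features_of",
    "collapse_by_symbol",
    "reverse_complement",
    "spliced_sequence",
    "genomic_to_transcript",
    "transcript_to_genomic",
    "transcript_blocks",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomePosition:
    """A stranded 1-based position on a chromosome."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.strand}{self.chrom}:{self.pos}"


@dataclass(frozen=True, order=True)
class Junction:
    """Directed donor→acceptor pair of stranded genomic positions.

    ``donor.pos`` is the last base of the preserved donor side and
    ``acceptor.pos`` the first base of the preserved acceptor side.
    """

    donor: GenomePosition
    acceptor: GenomePosition

    def __str__(self) -> str:
        return format_junction_string(self)


_JUNCTION_RE = re.compile(
    r"^(?P<dstrand>[+-])(?P<dchrom>[^:>\s]+):(?P<dpos>\d+)"
    r"->"
    r"(?P<astrand>[+-])(?P<achrom>[^:>\s]+):(?P<apos>\d+)$"
)


def parse_junction_string(s: str) -> Junction:
    """Parse the canonical junction notation, e.g. ``+chr17:5250220->+chr17:11532734``."""
    m = _JUNCTION_RE.match(s.strip())
    if m is None:
        # point at the offending half for a usable message
        if "->" not in s:
            raise ValueError(f"malformed junction string (missing '->'): {s!r}")
        left, _, right = s.partition("->")
        side = left if not re.match(r"^[+-][^:>\s]+:\d+$", left.strip()) else right
        raise ValueError(f"malformed junction string at {side.strip()!r} in {s!r}")
    return Junction(
        donor=GenomePosition(m["dchrom"], int(m["dpos"]), m["dstrand"]),
        acceptor=GenomePosition(m["achrom"], int(m["apos"]), m["astrand"]),
    )


def format_junction_string(j: Junction) -> str:
    return f"{j.donor}->{j.acceptor}"


@dataclass
class GeneModel:
    """A stranded gene/transcript with ordered exons and optional CDS bounds.

    ``exons`` are 1-based inclusive intervals sorted by genomic coordinate;
    ``cds_start``/``cds_end`` are genomic bounds of the coding span (None for
    non-coding transcripts).
    """

    name: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None
    cds_end: int | None
    exons: list[tuple[int, int]]
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.name}: overlapping exons ({s1},{e1}) ({s2},{e2})")
        if self.exons and (self.tx_start > self.exons[0][0] or self.tx_end < self.exons[-1][1]):
            raise ValueError(f"{self.name}: tx span does not cover exons")

    @property
    def coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def introns(self) -> list[tuple[int, int]]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class Feature:
    """One exon or intron of a gene, numbered in transcription order (1 = 5'-most)."""

    gene: str
    kind: str  # "exon" | "intron"
    ordinal: int
    interval: tuple[int, int]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1

    @property
    def id(self) -> str:
        return f"{self.gene}|{self.kind}{self.ordinal}"


def features_of(gene: GeneModel) -> list[Feature]:
    """Exons and introns of ``gene`` in transcription order.

    For minus-strand genes ordinal 1 is the genomically rightmost exon.
    """
    if not gene.exons:
        raise ValueError(f"{gene.name}: gene has no exons")
    sym = gene.symbol
    exons = gene.exons
    introns = gene.introns()
    feats: list[Feature] = []
    n = len(exons)
    if gene.strand == "+":
        for i in range(n):
            feats.append(Feature(sym, "exon", i + 1, exons[i]))
            if i < n - 1:
                feats.append(Feature(sym, "intron", i + 1, introns[i]))
    else:
        for i in range(n):
            feats.append(Feature(sym, "exon", i + 1, exons[n - 1 - i]))
            if i < n - 1:
                feats.append(Feature(sym, "intron", i + 1, introns[n - 2 - i]))
    return feats


# ---------------------------------------------------------------------------
# refGene (UCSC tab dialect) reading and writing
# ---------------------------------------------------------------------------

def _split_coord_list(text: str, line_no: int, what: str) -> list[int]:
    items = [t for t in text.strip().split(",") if t]
    try:
        return [int(t) for t in items]
    except ValueError as exc:
        raise ValueError(f"refGene line {line_no}: bad {what} list {text!r}") from exc


def parse_refgene(path: str, pseudogene_ids: Iterable[str] = ()) -> list[GeneModel]:
    """Parse a UCSC refGene table into :class:`GeneModel` objects.

    The file is tab separated with a leading ``bin`` column (a variant without
    it is also accepted), coordinates 0-based half-open; they are converted to
    1-based inclusive here.  ``pseudogene_ids`` is an optional id/symbol list
    used to set the pseudogene flag (refGene itself carries no such column).
    """
    pseudo = set(pseudogene_ids)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            # with bin: name at col 1; without: name at col 0 (strand at col 3 vs 2)
            if len(cols) >= 16 and cols[3] in "+-":
                cols = cols[1:]
            elif len(cols) < 11 or cols[2] not in "+-":
                raise ValueError(f"refGene line {line_no}: unexpected column count {len(cols)}")
            (name, chrom, strand, tx_s, tx_e, cds_s, cds_e, exon_count, e_starts, e_ends) = cols[:10]
            symbol = cols[11] if len(cols) > 11 else name
            starts = _split_coord_list(e_starts, line_no, "exonStarts")
            ends = _split_coord_list(e_ends, line_no, "exonEnds")
            if not (len(starts) == len(ends) == int(exon_count)):
                raise ValueError(
                    f"refGene line {line_no}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            cds_s_i, cds_e_i = int(cds_s), int(cds_e)
            coding = cds_e_i > cds_s_i
            genes.append(
                GeneModel(
                    name=name,
                    symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_s) + 1,
                    tx_end=int(tx_e),
                    cds_start=cds_s_i + 1 if coding else None,
                    cds_end=cds_e_i if coding else None,
                    exons=[(s + 1, e) for s, e in zip(starts, ends)],
                    is_pseudogene=name in pseudo or symbol in pseudo,
                )
            )
    return genes


def write_refgene(genes: Iterable[GeneModel], path: str) -> None:
    """Write GeneModels as a UCSC refGene table (0-based half-open, with bin column)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.coding:
                cds_s, cds_e = g.cds_start - 1, g.cds_end
            else:
                # UCSC convention for non-coding: cdsStart == cdsEnd == txEnd
                cds_s = cds_e = g.tx_end
            starts = "".join(f"{s - 1}," for s, _ in g.exons)
            ends = "".join(f"{e}," for _, e in g.exons)
            frames = "".join("-1," for _ in g.exons)
            row = [
                "0", g.name, g.chrom, g.strand,
                str(g.tx_start - 1), str(g.tx_end), str(cds_s), str(cds_e),
                str(len(g.exons)), starts, ends,
                "0", g.symbol, "unk", "unk", frames,
            ]
            fh.write("\t".join(row) + "\n")


def collapse_by_symbol(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Collapse transcripts sharing a gene symbol to one union-of-exons model.

    Junction annotation and feature counting work on these collapsed models;
    per-transcript models are kept separately for reading-frame prediction.
    Transcripts of one symbol on different chromosomes/strands are collapsed
    per (symbol, chrom, strand) and suffixed to stay unambiguous.
    """
    groups: dict[tuple[str, str, str], list[GeneModel]] = {}
    for g in genes:
        groups.setdefault((g.symbol, g.chrom, g.strand), []).append(g)
    seen: dict[str, int] = {}
    out: dict[str, GeneModel] = {}
    for (symbol, chrom, strand), members in groups.items():
        n = seen.get(symbol, 0)
        seen[symbol] = n + 1
        key = symbol if n == 0 else f"{symbol}__{n + 1}"
        intervals = sorted(iv for g in members for iv in g.exons)
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cds = [(g.cds_start, g.cds_end) for g in members if g.coding]
        out[key] = GeneModel(
            name=key,
            symbol=key,
            chrom=chrom,
            strand=strand,
            tx_start=min(g.tx_start for g in members),
            tx_end=max(g.tx_end for g in members),
            cds_start=min(c[0] for c in cds) if cds else None,
            cds_end=max(c[1] for c in cds) if cds else None,
            exons=[(s, e) for s, e in merged],
            is_pseudogene=all(g.is_pseudogene for g in members),
        )
    return out


# ---------------------------------------------------------------------------
# Genome sequence access
# ---------------------------------------------------------------------------

class Genome:
    """In-memory genome: chromosome name → uppercase sequence string.

    Toy genomes here are a few megabases, so whole-sequence residency is the
    simplest correct store; ``fetch`` is 1-based inclusive and strand-aware.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of ``[start, end]`` (1-based inclusive).

        ``strand='-'`` returns the reverse complement (sequence read 5'→3' on
        the bottom strand).
        """
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"coordinates {chrom}:{start}-{end} out of range (length {len(seq)})"
            )
        sub = seq[start - 1 : end]
        return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# Transcript-coordinate helpers (spliced sequence and coordinate maps)
# ---------------------------------------------------------------------------

def _tx_exons(gene: GeneModel) -> list[tuple[int, int]]:
    """Exons in transcription order (genomic intervals still (low, high))."""
    return gene.exons if gene.strand == "+" else list(reversed(gene.exons))


def spliced_sequence(genome: Genome, gene: GeneModel) -> str:
    """The mature (intron-free) transcript sequence, 5'→3'."""
    parts = [genome.fetch(gene.chrom, s, e, gene.strand) for s, e in _tx_exons(gene)]
    return "".join(parts)


def genomic_to_transcript(gene: GeneModel, pos: int) -> int | None:
    """Map a genomic position to a 1-based spliced-transcript coordinate.

    Returns None for intronic / out-of-gene positions.
    """
    t = 0
    for s, e in _tx_exons(gene):
        if s <= pos <= e:
            off = (pos - s) if gene.strand == "+" else (e - pos)
            return t + off + 1
        t += e - s + 1
    return None


def transcript_to_genomic(gene: GeneModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` (tpos is 1-based)."""
    if tpos < 1:
        raise ValueError("transcript position must be >= 1")
    t = 0
    for s, e in _tx_exons(gene):
        length = e - s + 1
        if tpos <= t + length:
            off = tpos - t - 1
            return s + off if gene.strand == "+" else e - off
        t += length
    raise ValueError(f"transcript position {tpos} beyond spliced length of {gene.name}")


def transcript_blocks(gene: GeneModel, t_lo: int, t_hi: int) -> list[tuple[int, int]]:
    """Genomic intervals covered by the spliced-transcript slice [t_lo, t_hi]."""
    if t_lo > t_hi:
        return []
    blocks: list[tuple[int, int]] = []
    t = 0
    for s, e in _tx_exons(gene):
        length = e - s + 1
        lo = max(t_lo, t + 1)
        hi = min(t_hi, t + length)
        if lo <= hi:
            if gene.strand == "+":
                blocks.append((s + (lo - t - 1), s + (hi - t - 1)))
            else:
                blocks.append((e - (hi - t - 1), e - (lo - t - 1)))
        t += length
    return blocks
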