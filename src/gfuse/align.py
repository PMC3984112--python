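"""Read filtering, split-read discovery and exon/intron base counting.

The aligner here is a deliberately small seed-and-extend design (k-mer seed
index, per-diagonal extension, two-segment chaining) sized for toy genomes of
a few megabases.  It reports three alignment kinds for a 50 bp read:

``local``
    one contiguous segment;
``local_spliced``
    two segments on the same chromosome and strand in transcription-consistent
    order separated by less than 1 Mb (an ordinary splice);
``distant_spliced``
    two segments anywhere — different chromosomes, strands, opposite order, or
    far apart — the raw material of fusion-junction discovery.

Scoring is match +1 / mismatch −1 with a flat penalty for introducing a splice,
so a contiguous placement is always preferred over an equally good split one.
For real cohorts the module ingests SAM with supplementary alignments instead
of running this aligner.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome_model import Feature, GeneModel, Genome, features_of

__all__ = [
    "Read",
    "Segment",
    "SegmentAlignment",
    "SeqIndex",
    "FeatureIndex",
    "GeneTable",
    "encode",
    "revcomp_codes",
    "load_fastq",
    "quality_filter",
    "abundance_filter",
    "map_read",
    "retest_distant_read",
    "count_features",
    "write_sam",
    "read_sam",
]

# match +1, mismatch -1; flat cost for opening a splice within a read
MATCH = 1
MISMATCH = -1
SPLICE_PENALTY = 3
MIN_SEGMENT = 10
MAX_LOCAL_GAP = 1_000_000

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC[codes][::-1]


@dataclass
class Read:
    id: str
    seq: str
    quals: np.ndarray  # phred scores, uint8, same length as seq

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.id}: sequence and quality lengths differ")


def load_fastq(path: str) -> list[Read]:
    reads = []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            quals = np.frombuffer(rec.quality.encode("ascii"), dtype=np.uint8) - 33
            reads.append(Read(rec.name, rec.sequence.upper(), quals))
    return reads


@dataclass(frozen=True)
class Segment:
    """One aligned block of a read.

    Genomic coordinates are 1-based inclusive on the top strand; query
    coordinates are 0-based inclusive positions in the read as sequenced.
    ``mismatches`` are query positions of aligned-but-mismatching bases.
    """

    chrom: str
    strand: str
    gstart: int
    gend: int
    qstart: int
    qend: int
    mismatches: tuple[int, ...] = ()


@dataclass(frozen=True)
class SegmentAlignment:
    read_id: str
    segments: tuple[Segment, ...]
    kind: str  # local | local_spliced | distant_spliced
    unique: bool
    score: int

    def matched_bases(self) -> int:
        return sum(s.qend - s.qstart + 1 - len(s.mismatches) for s in self.segments)


# ---------------------------------------------------------------------------
# k-mer seed index over a set of named sequences
# ---------------------------------------------------------------------------

class SeqIndex:
    """Exact k-mer position index over named sequences (genome, blacklist or
    template collections all use the same machinery).

    Sequences are concatenated with runs of N so that no seed and no matched
    base can span two sequences.  Lookup returns candidate *window starts*
    (global, possibly out of bounds at the edges) for an encoded query.
    """

    PAD = 60

    def __init__(self, sequences: dict[str, str], k: int = 15):
        self.k = k
        self.names = list(sequences)
        parts: list[np.ndarray] = []
        self._starts = np.zeros(len(self.names), dtype=np.int64)
        self._lengths = np.zeros(len(self.names), dtype=np.int64)
        pad = np.full(self.PAD, 4, dtype=np.uint8)
        pos = 0
        for i, name in enumerate(self.names):
            codes = encode(sequences[name])
            self._starts[i] = pos
            self._lengths[i] = len(codes)
            parts.append(codes)
            parts.append(pad)
            pos += len(codes) + self.PAD
        self.codes = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self._build()

    def _build(self) -> None:
        codes, k = self.codes, self.k
        n = len(codes)
        if n < k:
            self._sorted_vals = np.zeros(0, dtype=np.int64)
            self._sorted_pos = np.zeros(0, dtype=np.int64)
            return
        vals = np.zeros(n - k + 1, dtype=np.int64)
        for j in range(k):
            vals *= 4
            vals += codes[j : j + n - k + 1]
        bad = np.concatenate([[0], np.cumsum((codes >= 4).astype(np.int64))])
        ok = (bad[k:] - bad[:-k]) == 0
        positions = np.nonzero(ok)[0]
        vals = vals[positions]
        order = np.argsort(vals, kind="stable")
        self._sorted_vals = vals[order]
        self._sorted_pos = positions[order]

    def query_kmers(self, codes: np.ndarray) -> np.ndarray:
        k = self.k
        n = len(codes)
        if n < k:
            return np.zeros(0, dtype=np.int64)
        vals = np.zeros(n - k + 1, dtype=np.int64)
        for j in range(k):
            vals *= 4
            vals += codes[j : j + n - k + 1]
        bad = np.concatenate([[0], np.cumsum((codes >= 4).astype(np.int64))])
        has_n = (bad[k:] - bad[:-k]) > 0
        vals[has_n] = -1  # never present in the index
        return vals

    def candidates(self, codes: np.ndarray) -> list[int]:
        """Unique candidate window starts: positions g such that placing the
        full query at concat offset g is supported by at least one exact seed."""
        vals = self.query_kmers(codes)
        if len(vals) == 0:
            return []
        lo = np.searchsorted(self._sorted_vals, vals, side="left")
        hi = np.searchsorted(self._sorted_vals, vals, side="right")
        out: set[int] = set()
        for off in np.nonzero(hi > lo)[0]:
            for p in self._sorted_pos[lo[off] : hi[off]]:
                out.add(int(p) - int(off))
        return sorted(out)

    def matchvec(self, g: int, codes: np.ndarray) -> np.ndarray:
        """Per-base equality of the query placed at concat offset ``g``
        (positions outside the concatenation count as mismatches)."""
        L = len(codes)
        out = np.zeros(L, dtype=bool)
        lo = max(g, 0)
        hi = min(g + L, len(self.codes))
        if hi > lo:
            out[lo - g : hi - g] = self.codes[lo:hi] == codes[lo - g : hi - g]
        return out

    def locate(self, g: int) -> tuple[str, int]:
        """Concat offset → (sequence name, 1-based position)."""
        i = int(np.searchsorted(self._starts, g, side="right")) - 1
        if i < 0 or g - self._starts[i] >= self._lengths[i]:
            raise ValueError(f"concat offset {g} falls outside every sequence")
        return self.names[i], int(g - self._starts[i]) + 1

    def seq_bounds(self, g: int) -> tuple[int, int]:
        """Concat-coordinate [start, end) of the sequence containing ``g``."""
        i = int(np.searchsorted(self._starts, g, side="right")) - 1
        return int(self._starts[i]), int(self._starts[i] + self._lengths[i])

    def global_of(self, name: str, pos: int) -> int:
        i = self.names.index(name)
        return int(self._starts[i]) + pos - 1


# ---------------------------------------------------------------------------
# Step-1 read filters
# ---------------------------------------------------------------------------

def quality_filter(read: Read, min_bases: int = 15, min_quality: int = 20) -> bool:
    """Keep a read iff at least ``min_bases`` bases (at any position) have a
    base quality of ``min_quality`` or above."""
    return int((read.quals >= min_quality).sum()) >= min_bases


def abundance_filter(read: Read, blacklist: SeqIndex, min_match: int = 45) -> bool:
    """Keep (True) unless the read aligns to an abundant/contaminant sequence
    (rRNA-like, PhiX-like ...) with ``min_match`` or more matching bases on
    either strand."""
    codes = encode(read.seq)
    for c in (codes, revcomp_codes(codes)):
        for g in blacklist.candidates(c):
            if int(blacklist.matchvec(g, c).sum()) >= min_match:
                return False
    return True


# ---------------------------------------------------------------------------
# Seed-and-extend mapping
# ---------------------------------------------------------------------------

def _read_coord_matchvec(index: SeqIndex, strand: str, g: int, codes: np.ndarray,
                         rc: np.ndarray) -> np.ndarray:
    """Match vector indexed by READ position for window start g on a strand."""
    if strand == "+":
        return index.matchvec(g, codes)
    return index.matchvec(g, rc)[::-1]


def _global_of_read_pos(strand: str, g: int, L: int, q: int) -> int:
    return g + q if strand == "+" else g + L - 1 - q


def _make_segment(index: SeqIndex, strand: str, g: int, L: int, q0: int, q1: int,
                  mv: np.ndarray) -> Segment | None:
    """Build a Segment for read span [q0, q1] on diagonal g, clipping read
    bases whose positions fall outside the sequence that holds the matches."""
    matched_q = np.nonzero(mv[q0 : q1 + 1])[0]
    if len(matched_q) == 0:
        return None
    core_q = q0 + int(matched_q[len(matched_q) // 2])
    core_g = _global_of_read_pos(strand, g, L, core_q)
    lo, hi = index.seq_bounds(core_g)
    # clip query span so every aligned base stays inside [lo, hi)
    while q0 <= q1 and not (lo <= _global_of_read_pos(strand, g, L, q0) < hi):
        q0 += 1
    while q1 >= q0 and not (lo <= _global_of_read_pos(strand, g, L, q1) < hi):
        q1 -= 1
    if q0 > q1:
        return None
    ga = _global_of_read_pos(strand, g, L, q0)
    gb = _global_of_read_pos(strand, g, L, q1)
    gstart, gend = min(ga, gb), max(ga, gb)
    chrom, pos = index.locate(gstart)
    mism = tuple(int(q) for q in range(q0, q1 + 1) if not mv[q])
    return Segment(chrom, strand, pos, pos + (gend - gstart), q0, q1, mism)


def map_read(read: Read, index: SeqIndex, *, min_seg: int = MIN_SEGMENT,
             splice_penalty: int = SPLICE_PENALTY,
             max_local_gap: int = MAX_LOCAL_GAP) -> list[SegmentAlignment]:
    """Best-scoring placement of a read: contiguous, locally spliced or
    distant-spliced.  Returns [] for unmappable reads.

    A read carrying a planted junction with at least k+5 exact bases on each
    side and at most one mismatch per segment is reported distant_spliced at
    the exact junction; ``unique`` is True iff exactly one placement achieves
    the best score.
    """
    codes = encode(read.seq)
    L = len(codes)
    if L < index.k:
        return []
    rc = revcomp_codes(codes)
    cands: list[tuple[str, int]] = []
    mvs: list[np.ndarray] = []
    for strand, c in (("+", codes), ("-", rc)):
        for g in index.candidates(c):
            cands.append((strand, g))
            mvs.append(_read_coord_matchvec(index, strand, g, codes, rc))
    if not cands:
        return []
    match_counts = np.array([int(mv.sum()) for mv in mvs])
    best_m = int(match_counts.max())
    local_best_score = 2 * best_m - L

    def _local_alignment() -> list[SegmentAlignment]:
        winners = np.nonzero(match_counts == best_m)[0]
        i = int(winners[0])
        strand, g = cands[i]
        seg = _make_segment(index, strand, g, L, 0, L - 1, mvs[i])
        if seg is None:
            return []
        return [SegmentAlignment(read.id, (seg,), "local", len(winners) == 1,
                                 local_best_score)]

    # fast path: near-perfect contiguous placement cannot be beaten by a split
    if best_m >= L - 2:
        return _local_alignment()

    n = len(cands)
    arr = np.stack(mvs).astype(np.int32)
    cums = np.zeros((n, L + 1), dtype=np.int32)
    np.cumsum(arr, axis=1, out=cums[:, 1:])
    b_lo, b_hi = min_seg, L - min_seg
    if b_hi < b_lo:
        return _local_alignment()
    bs = np.arange(b_lo, b_hi + 1)
    pref_sc = 2 * cums[:, bs] - bs            # (n, nb)
    suf_sc = 2 * (cums[:, [L]] - cums[:, bs]) - (L - bs)
    best1 = pref_sc.max(axis=0)
    best2 = suf_sc.max(axis=0)
    totals = best1 + best2 - splice_penalty
    best_total = int(totals.max())
    if best_total <= local_best_score:
        return _local_alignment()

    # collect distinct locus pairs achieving the best total (microhomology
    # shifts of the same pair are one placement, counted once)
    placements: set[tuple[int, int]] = set()
    for bi in np.nonzero(totals == best_total)[0]:
        for c1 in np.nonzero(pref_sc[:, bi] == best1[bi])[0]:
            for c2 in np.nonzero(suf_sc[:, bi] == best2[bi])[0]:
                if cands[c1] == cands[c2]:
                    continue  # same diagonal: that is just a contiguous placement
                placements.add((int(c1), int(c2)))
    if not placements:
        return _local_alignment()
    # canonical split: the largest b (donor extended as far as it matches)
    bi = int(np.nonzero(totals == best_total)[0][-1])
    b = int(bs[bi])
    c1 = int(pref_sc[:, bi].argmax())
    c2 = int(suf_sc[:, bi].argmax())
    if cands[c1] == cands[c2]:  # best pair at canonical b collapses; try others
        pair = sorted(placements)[0]
        c1, c2 = pair
    strand1, g1 = cands[c1]
    strand2, g2 = cands[c2]
    seg1 = _make_segment(index, strand1, g1, L, 0, b - 1, mvs[c1])
    seg2 = _make_segment(index, strand2, g2, L, b, L - 1, mvs[c2])
    if seg1 is None or seg2 is None:
        return _local_alignment()
    if strand1 == strand2 and seg1.chrom == seg2.chrom:
        if strand1 == "+":
            consistent = g2 > g1
        else:
            consistent = g2 < g1
        gap = abs(g2 - g1)
        kind = "local_spliced" if (consistent and gap < max_local_gap) else "distant_spliced"
    else:
        kind = "distant_spliced"
    return [SegmentAlignment(read.id, (seg1, seg2), kind, len(placements) == 1,
                             best_total)]


def junction_of(aln: SegmentAlignment) -> tuple[str, int, str, str, int, str]:
    """(chrom, pos, strand) of donor (last base of segment 1 in read order)
    and acceptor (first base of segment 2) for a two-segment alignment."""
    s1, s2 = aln.segments
    dpos = s1.gend if s1.strand == "+" else s1.gstart
    apos = s2.gstart if s2.strand == "+" else s2.gend
    return (s1.chrom, dpos, s1.strand, s2.chrom, apos, s2.strand)


# ---------------------------------------------------------------------------
# Step-2 retest: does the read realign to a single locus after all?
# ---------------------------------------------------------------------------

def retest_distant_read(read: Read, index: SeqIndex, *, min_match: int = 44,
                        max_gap: int = 1) -> bool:
    """Re-align a distant-spliced read favouring a single locus; keep (True)
    unless some locus explains it with ``min_match`` matched bases allowing at
    most one gap of ``max_gap`` (=1) base.

    A pseudo-chimera manufactured by splitting a contiguous genomic 50-mer
    realigns with ~50 matches and is discarded; a genuine fusion read matches
    any single locus on only one side and is kept.
    """
    codes = encode(read.seq)
    L = len(codes)
    rc = revcomp_codes(codes)
    best = 0
    for c in (codes, rc):
        for g in index.candidates(c):
            mv0 = index.matchvec(g, c)
            cum0 = np.concatenate([[0], np.cumsum(mv0)])
            best = max(best, int(cum0[L]))
            if max_gap >= 1:
                mvp = index.matchvec(g + 1, c)
                mvm = index.matchvec(g - 1, c)
                cump = np.concatenate([[0], np.cumsum(mvp)])
                cumm = np.concatenate([[0], np.cumsum(mvm)])
                i = np.arange(L + 1)
                # one reference base skipped at read offset i
                del_best = int((cum0[i] + (cump[L] - cump[i])).max())
                # one read base (i) left unaligned
                j = np.arange(L)
                ins_best = int((cum0[j] + (cumm[L] - cumm[j + 1])).max())
                best = max(best, del_best, ins_best)
            if best >= min_match:
                return False
    return best < min_match


# ---------------------------------------------------------------------------
# Gene tables: per-sample base counts over exon/intron features
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Interval lookup from genomic position to exon/intron features."""

    def __init__(self, gene_models: dict[str, GeneModel]):
        self.features: list[Feature] = []
        self.chrom_of: dict[str, str] = {}
        self._trees: dict[str, IntervalTree] = {}
        for gene in gene_models.values():
            for feat in features_of(gene):
                idx = len(self.features)
                self.features.append(feat)
                self.chrom_of[feat.id] = gene.chrom
                tree = self._trees.setdefault(gene.chrom, IntervalTree())
                tree.addi(feat.interval[0], feat.interval[1] + 1, idx)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[Feature, int]]:
        """Features overlapping [start, end] with the overlap length in bases."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(start, end + 1):
            feat = self.features[iv.data]
            ov = min(end, feat.interval[1]) - max(start, feat.interval[0]) + 1
            out.append((feat, ov))
        return out


def count_features(alignments: Iterable[SegmentAlignment], findex: FeatureIndex,
                   ) -> tuple[dict[str, int], int]:
    """Sum aligned-base overlap per feature over uniquely mapped alignments.

    Returns (counts by feature id, total aligned bases).  Non-unique
    alignments contribute nothing.
    """
    counts: dict[str, int] = {}
    total = 0
    for aln in alignments:
        if not aln.unique:
            continue
        for seg in aln.segments:
            total += seg.qend - seg.qstart + 1
            for feat, ov in findex.overlapping(seg.chrom, seg.gstart, seg.gend):
                counts[feat.id] = counts.get(feat.id, 0) + ov
    return counts, total


class GeneTable:
    """Base-count matrix over exon/intron features × samples ("gene table")."""

    def __init__(self, features: list[Feature]):
        self.features = features
        self.df = pd.DataFrame(index=[f.id for f in features], dtype=float)
        self.library_total: dict[str, int] = {}

    def add_sample(self, sample: str, counts: dict[str, int], library_total: int) -> None:
        col = pd.Series(0.0, index=self.df.index)
        for fid, c in counts.items():
            if fid in col.index:
                col[fid] = c
        self.df[sample] = col
        self.library_total[sample] = library_total

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def to_tsv(self, path: str) -> None:
        out = self.df.copy()
        out.insert(0, "length", [f.length for f in self.features])
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str, gene_models: dict[str, GeneModel]) -> "GeneTable":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        feats = [f for g in gene_models.values() for f in features_of(g)]
        table = cls([f for f in feats if f.id in df.index])
        table.df = df.drop(columns=["length"]).reindex([f.id for f in table.features])
        table.library_total = {s: int(table.df[s].sum()) for s in table.df.columns}
        return table


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------

def _sam_header(genome: Genome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()],
    })


def write_sam(path: str, genome: Genome, reads: Sequence[Read],
              alignments: dict[str, list[SegmentAlignment]]) -> None:
    """Export alignments as SAM.  Split reads become two records sharing the
    read id, the second with the supplementary flag; MAPQ encodes uniqueness
    (60 unique, 0 otherwise); unaligned reads are emitted unmapped."""
    header = _sam_header(genome)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            alns = alignments.get(read.id, [])
            if not alns:
                rec = pysam.AlignedSegment(header)
                rec.query_name = read.id
                rec.is_unmapped = True
                rec.query_sequence = read.seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.quals))
                out.write(rec)
                continue
            for aln in alns:
                for si, seg in enumerate(aln.segments):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = read.id
                    rec.reference_id = header.references.index(seg.chrom)
                    rec.reference_start = seg.gstart - 1
                    rec.mapping_quality = 60 if aln.unique else 0
                    rec.is_reverse = seg.strand == "-"
                    rec.is_supplementary = si > 0
                    L = len(read.seq)
                    nmatch = seg.qend - seg.qstart + 1
                    pre, post = seg.qstart, L - 1 - seg.qend
                    if seg.strand == "-":
                        pre, post = post, pre
                        rec.query_sequence = _revcomp_str(read.seq)
                        rec.query_qualities = list(read.quals[::-1])
                    else:
                        rec.query_sequence = read.seq
                        rec.query_qualities = list(read.quals)
                    cigar = []
                    if pre:
                        cigar.append((4, pre))
                    cigar.append((0, nmatch))
                    if post:
                        cigar.append((4, post))
                    rec.cigartuples = cigar
                    rec.set_tag("XK", aln.kind)
                    if seg.mismatches:
                        # query positions of mismatches (plain SAM has no MD here)
                        rec.set_tag("XZ", ",".join(map(str, seg.mismatches)))
                    out.write(rec)


def _revcomp_str(seq: str) -> str:
    from .genome_model import reverse_complement
    return reverse_complement(seq)


def read_sam(path: str) -> tuple[dict[str, list[SegmentAlignment]], list[str]]:
    """Ingest SAM produced by :func:`write_sam` (or an external split-read
    aligner using supplementary records).  Mismatch positions are not
    recoverable from plain SAM and are left empty.  Returns (alignments by
    read id, unmapped read ids)."""
    by_read: dict[str, list[tuple[bool, Segment, bool, str | None]]] = {}
    unmapped: list[str] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                unmapped.append(rec.query_name)
                continue
            L = rec.infer_read_length() or len(rec.query_sequence or "")
            pre = rec.cigartuples[0][1] if rec.cigartuples[0][0] in (4, 5) else 0
            nmatch = sum(n for op, n in rec.cigartuples if op in (0, 7, 8))
            strand = "-" if rec.is_reverse else "+"
            if strand == "+":
                qstart = pre
            else:
                qstart = L - pre - nmatch
            mism: tuple[int, ...] = ()
            if rec.has_tag("XZ"):
                mism = tuple(int(x) for x in str(rec.get_tag("XZ")).split(",") if x)
            seg = Segment(rec.reference_name, strand, rec.reference_start + 1,
                          rec.reference_start + nmatch, qstart, qstart + nmatch - 1,
                          mism)
            kind = rec.get_tag("XK") if rec.has_tag("XK") else None
            by_read.setdefault(rec.query_name, []).append(
                (rec.is_supplementary, seg, rec.mapping_quality > 0, kind))
    out: dict[str, list[SegmentAlignment]] = {}
    for rid, entries in by_read.items():
        entries.sort(key=lambda t: (t[0], t[1].qstart))
        segs = tuple(sorted((e[1] for e in entries), key=lambda s: s.qstart))
        unique = all(e[2] for e in entries)
        kind = next((e[3] for e in entries if e[3]), None)
        if kind is None:
            if len(segs) == 1:
                kind = "local"
            else:
                s1, s2 = segs
                same = s1.chrom == s2.chrom and s1.strand == s2.strand
                if same:
                    if s1.strand == "+":
                        consistent = s2.gstart > s1.gstart
                    else:
                        consistent = s2.gstart < s1.gstart
                    gap = abs(s2.gstart - s1.gstart)
                    kind = "local_spliced" if consistent and gap < MAX_LOCAL_GAP else "distant_spliced"
                else:
                    kind = "distant_spliced"
        score = sum(s.qend - s.qstart + 1 for s in segs)
        out[rid] = [SegmentAlignment(rid, segs, kind, unique, score)]
    return out, unmapped
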