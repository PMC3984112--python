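"""Template remapping and expression-discontinuity profiling.

Per library, the reads worth re-examining (those mapped near any template
flank, plus everything unmapped) are re-aligned — contiguously, no splicing —
against the pooled template index.  A read supports a fusion only if it maps
uniquely to the *fusion* template, overhangs the junction midpoint by at least
6 bases and is mismatch-free within that overhang.

Expression evidence comes from the gene tables: per-library DESeq-style
median-of-ratios size factors, a count floor of 5, per-length coverage, and
the Interrupt Ratio (IR) — mean preserved-side coverage over mean
discarded-side coverage for the donor and acceptor of each candidate, with the
breakpoint-adjacent intron excluded (its breaking point is unknown).  Samples
of a cohort are ranked by IR and flagged "interrupted" when their IR stands
out against the cohort.  Cohorts are profiled separately even though the
template index is pooled across them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import GeneTable, Read, SegmentAlignment, SeqIndex, encode, quality_filter, revcomp_codes
from .genome_model import GeneModel, Junction, features_of
from .templates import TemplateIndex

__all__ = [
    "TemplateHit",
    "ExpressionEvidence",
    "COUNT_FLOOR",
    "MIN_JUNCTION_OVERHANG",
    "select_reads_for_remap",
    "remap_to_templates",
    "fusion_support_reads",
    "size_factors",
    "interrupt_ratio",
    "nominate_interrupted",
    "center_scaled_matrix",
]

COUNT_FLOOR = 5.0            # features below 5 are padded to 5
MIN_JUNCTION_OVERHANG = 6    # bases required on the short side of the junction
REMAP_MIN_MATCH_FRACTION = 0.9


@dataclass(frozen=True)
class TemplateHit:
    read_id: str
    sample: str
    junction: str
    role: str                   # fusion | donor | acceptor | donor_pre | acceptor_pre
    offset: int                 # 0-based read start within the template
    strand: str
    matches: int
    unique_best: bool
    junction_overhang: int      # min bases on either side of the template midpoint
    mismatch_tpos: tuple[int, ...]  # template positions (1-based) of mismatches
    read_seq: str


@dataclass
class ExpressionEvidence:
    junction: str
    sample: str
    ir_donor: float | None
    ir_acceptor: float | None
    cohort_rank: int
    interrupted: bool

    @property
    def max_ir(self) -> float | None:
        vals = [v for v in (self.ir_donor, self.ir_acceptor) if v is not None]
        return max(vals) if vals else None


# ---------------------------------------------------------------------------
# Step 5: read retrieval and remapping
# ---------------------------------------------------------------------------

def select_reads_for_remap(read_intervals: dict[str, list[tuple[str, int, int]]],
                           unmapped_ids: set[str],
                           flank_blocks: list[tuple[int, int, str]],
                           read_len: int = 50) -> set[str]:
    """Read ids whose genomic alignment overlaps any template flank padded by
    the read length, plus every unmapped read."""
    trees: dict[str, IntervalTree] = {}
    for start, end, chrom in flank_blocks:
        trees.setdefault(chrom, IntervalTree()).addi(
            max(start - read_len, 0), end + read_len + 1)
    selected = set(unmapped_ids)
    for rid, ivs in read_intervals.items():
        for chrom, s, e in ivs:
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps(s, e + 1):
                selected.add(rid)
                break
    return selected


def remap_to_templates(reads: list[Read], index: TemplateIndex, sample: str,
                       apply_quality_filter: bool = True) -> list[TemplateHit]:
    """Best contiguous full-length placement of each read over all pooled
    templates (splicing off).  ``unique_best`` is True iff exactly one
    (template, offset, strand) attains the best match count; reads matching
    fewer than 90% of their bases anywhere are dropped."""
    hits: list[TemplateHit] = []
    sidx = index.seq_index
    W = index.width
    for read in reads:
        if apply_quality_filter and not quality_filter(read):
            continue
        codes = encode(read.seq)
        L = len(codes)
        placements: list[tuple[int, str, int, np.ndarray]] = []
        for strand, c in (("+", codes), ("-", revcomp_codes(codes))):
            for g in sidx.candidates(c):
                try:
                    name, pos1 = sidx.locate(g)
                except ValueError:
                    continue
                offset = pos1 - 1
                if offset < 0 or offset > W - L:
                    continue
                mv = sidx.matchvec(g, c)
                placements.append((int(mv.sum()), strand, g, mv))
        if not placements:
            continue
        best = max(p[0] for p in placements)
        if best < int(math.ceil(REMAP_MIN_MATCH_FRACTION * L)):
            continue
        winners = [p for p in placements if p[0] == best]
        matches, strand, g, mv = winners[0]
        name, pos1 = sidx.locate(g)
        jkey, role = index.tags[name]
        offset = pos1 - 1
        mid = W // 2
        left = max(0, min(L, mid - offset))
        overhang = min(left, L - left)
        mism = tuple(offset + i + 1 for i in np.nonzero(~mv)[0])
        hits.append(TemplateHit(
            read_id=read.id, sample=sample, junction=jkey, role=role,
            offset=offset, strand=strand, matches=matches,
            unique_best=len(winners) == 1, junction_overhang=overhang,
            mismatch_tpos=mism, read_seq=read.seq))
    return hits


def fusion_support_reads(hits: list[TemplateHit],
                         min_overhang: int = MIN_JUNCTION_OVERHANG,
                         width: int = 100) -> list[TemplateHit]:
    """Hits that count as fusion-junction support: uniquely best on the fusion
    template, spanning the junction by ≥ ``min_overhang`` bases on each side,
    with no mismatch inside the overhang window."""
    out = []
    mid = width // 2  # junction sits between template positions mid and mid+1
    for h in hits:
        if h.role != "fusion" or not h.unique_best:
            continue
        if h.junction_overhang < min_overhang:
            continue
        lo, hi = mid - h.junction_overhang + 1, mid + h.junction_overhang
        if any(lo <= t <= hi for t in h.mismatch_tpos):
            continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# Step 6: size factors and Interrupt Ratios
# ---------------------------------------------------------------------------

def size_factors(table: GeneTable | pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios library size factors.

    factor_j = median over features f of count(f, j) / geomean_samples(count(f, ·)),
    features with a zero geometric mean excluded from the median.
    """
    df = table.df if isinstance(table, GeneTable) else table
    if df.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    mat = df.to_numpy(dtype=float)
    valid = (mat > 0).all(axis=1)
    if not valid.any():
        raise ValueError("degenerate libraries: no feature counted in every sample")
    logs = np.log(mat[valid])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _classify_feature(feat_interval: tuple[int, int], strand: str, pos: int,
                      role: str) -> str:
    """'preserved' / 'discarded' / 'straddle' for one feature relative to a
    junction position.  Donor: preserved is 5' of (and including) pos;
    acceptor: preserved starts at pos."""
    s, e = feat_interval
    if role == "donor":
        if strand == "+":
            if e <= pos:
                return "preserved"
            if s > pos:
                return "discarded"
        else:
            if s >= pos:
                return "preserved"
            if e < pos:
                return "discarded"
        return "straddle"
    else:  # acceptor
        if strand == "+":
            if s >= pos:
                return "preserved"
            if e < pos:
                return "discarded"
        else:
            if e <= pos:
                return "preserved"
            if s > pos:
                return "discarded"
        return "straddle"


def _side_features(gene: GeneModel, pos: int, role: str
                   ) -> tuple[list, list]:
    """(preserved features, discarded features) in transcription order, with
    the breakpoint-adjacent intron — the intron immediately after the donor
    splice site, or immediately before the acceptor splice site — excluded,
    along with any feature the junction cuts through."""
    feats = features_of(gene)
    labels = [_classify_feature(f.interval, gene.strand, pos, role) for f in feats]
    preserved = [f for f, l in zip(feats, labels) if l == "preserved"]
    discarded = [f for f, l in zip(feats, labels) if l == "discarded"]
    if role == "donor":
        # transcription order puts the excluded intron first on the discarded side
        if discarded and discarded[0].kind == "intron":
            discarded = discarded[1:]
    else:
        if discarded and discarded[-1].kind == "intron":
            discarded = discarded[:-1]
    return preserved, discarded


def interrupt_ratio(junction: Junction, donor_gene: GeneModel,
                    acceptor_gene: GeneModel, table: GeneTable, sample: str,
                    factors: pd.Series, floor: float = COUNT_FLOOR
                    ) -> tuple[float | None, float | None]:
    """(IR_donor, IR_acceptor) for one sample.

    Per feature: normalised count max(raw/factor, floor), divided by feature
    length to give coverage; IR is mean preserved coverage over mean discarded
    coverage.  None marks an undefined ratio (a side with no usable feature).
    """
    col = table.df[sample]
    f = float(factors[sample])

    def mean_cov(feats) -> float | None:
        if not feats:
            return None
        covs = [max(float(col.get(ft.id, 0.0)) / f, floor) / ft.length for ft in feats]
        return float(np.mean(covs))

    out = []
    for gene, role, pos in ((donor_gene, "donor", junction.donor.pos),
                            (acceptor_gene, "acceptor", junction.acceptor.pos)):
        pres, disc = _side_features(gene, pos, role)
        num, den = mean_cov(pres), mean_cov(disc)
        out.append(None if num is None or den is None else num / den)
    return out[0], out[1]


def nominate_interrupted(ir_by_sample: dict[str, tuple[float | None, float | None]],
                         junction: str,
                         median_multiple: float = 3.0,
                         absolute_floor: float = 2.0
                         ) -> dict[str, ExpressionEvidence]:
    """Rank a cohort's samples by max(IR_donor, IR_acceptor) and flag those
    whose IR reaches max(``median_multiple`` × cohort median, ``absolute_floor``).
    A cohort of one sample is judged on the absolute floor alone."""
    max_irs = {}
    for s, (ird, ira) in ir_by_sample.items():
        vals = [v for v in (ird, ira) if v is not None]
        max_irs[s] = max(vals) if vals else None
    defined = [v for v in max_irs.values() if v is not None]
    if len(ir_by_sample) > 1 and defined:
        threshold = max(median_multiple * float(np.median(defined)), absolute_floor)
    else:
        threshold = absolute_floor
    ranking = sorted(max_irs, key=lambda s: -(max_irs[s] if max_irs[s] is not None else -np.inf))
    out = {}
    for rank, s in enumerate(ranking, 1):
        ird, ira = ir_by_sample[s]
        v = max_irs[s]
        out[s] = ExpressionEvidence(junction, s, ird, ira, rank,
                                    v is not None and v >= threshold)
    return out


def center_scaled_matrix(table: GeneTable, factors: pd.Series,
                         feature_ids: list[str]) -> pd.DataFrame:
    """Library-size-normalised counts for selected features, centered per
    feature across samples (rows sum to ~0) — heatmap-ready."""
    norm = table.df.loc[feature_ids].div(factors, axis=1)
    return norm.sub(norm.mean(axis=1), axis=0)


def export_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Optional image export of a center-scaled feature × sample matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, matrix.shape[1] * 0.5),
                                    max(3, matrix.shape[0] * 0.25)))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="centered normalised count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
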