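"""Synthetic FFPE-like cohort generator.

Emulates the data the pipeline was designed for: directional (strand-specific)
single-end 50 bp reads from heavily fragmented RNA (median fragment ~100 bp),
with a large intron-derived fraction (unspliced pre-mRNA molecules), a small
contaminant fraction drawn from abundant rRNA/PhiX-like sequences, and fusion
transcripts implanted at exon boundaries with a machine-readable truth set.

Everything is deterministic given the seed: the same config produces
byte-identical FASTA/refGene/FASTQ/truth files.

Design notes
------------
* Fragment lengths are log-normal (the real protocol states only the median);
  fragments shorter than the read length are dropped, mimicking adapter
  trimming of over-short inserts.
* Planted junctions are free of flanking microhomology: the generator owns the
  genome and, where the first discarded base next to a junction happens to
  equal the base across the junction, it edits that *discarded-side* base.
  Otherwise the junction coordinate is ambiguous at the RNA level and no
  read-based caller could report it exactly.
* A fusion's expression discontinuity is simulated as extra molecules of the
  donor-preserved and acceptor-preserved spliced segments, while
  junction-spanning reads are planted explicitly and exactly
  (``junction_reads_target`` is a count, not a rate) so that read-evidence
  tiers can be exercised precisely.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import (
    GeneModel,
    Genome,
    GenomePosition,
    Junction,
    format_junction_string,
    genomic_to_transcript,
    reverse_complement,
    spliced_sequence,
    transcript_to_genomic,
    write_refgene,
    _tx_exons,
)

__all__ = [
    "FusionSpec",
    "SimConfig",
    "TruthRecord",
    "CohortFiles",
    "fragment_lengths",
    "plan_genes",
    "build_fusion_mrna",
    "emit_reads",
    "build_toy_cohort",
    "default_demo_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """A simulation config references genes/exons that do not exist."""


@dataclass(frozen=True)
class FusionSpec:
    """One implanted fusion: donor exon `donor_exon` (transcription order) is
    spliced to acceptor exon `acceptor_exon` in the listed samples."""

    donor_gene: str
    donor_exon: int
    acceptor_gene: str
    acceptor_exon: int
    samples: tuple[str, ...]
    expression_fold: float = 20.0
    junction_reads_target: int = 4


@dataclass(frozen=True)
class TruthRecord:
    junction: str
    sample: str
    n_planted_junction_reads: int
    in_frame: bool


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 12
    n_genes: int = 20
    chrom_lengths: tuple[int, ...] = (2_400_000, 1_300_000)
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (200, 400)
    intron_length: tuple[int, int] = (400, 1200)
    fusions: tuple[FusionSpec, ...] = ()
    fragment_median_bp: int = 100
    fragment_sigma: float = 0.45
    read_len: int = 50
    # fraction of transcript molecules left unspliced; 0.65 puts the intronic
    # base fraction of emitted reads near 0.6, as in archival FFPE libraries
    premrna_fraction: float = 0.65
    contaminant_fraction: float = 0.05
    depth: int = 17_000
    directional: bool = True
    quality: int = 35

    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class CohortFiles:
    genome_fasta: str
    refgene: str
    blacklist_fasta: str
    fastqs: dict[str, str]
    truth_tsv: str
    genome: Genome
    genes: dict[str, GeneModel]
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------
# Fragment model
# ---------------------------------------------------------------------------

def fragment_lengths(n: int, median: float, rng: np.random.Generator,
                     sigma: float = 0.45, floor: int = 20) -> np.ndarray:
    """Log-normal fragment lengths with the distribution median pinned to
    ``median`` and a hard floor (shorter pieces are not recoverable)."""
    if n < 1:
        raise ValueError("need n >= 1")
    draws = median * np.exp(sigma * rng.standard_normal(n))
    return np.maximum(np.rint(draws).astype(int), floor)


# ---------------------------------------------------------------------------
# Genome / annotation planning
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n, dtype=np.uint8)]).decode()


def plan_genes(config: SimConfig) -> dict[str, GeneModel]:
    """Deterministic gene layout for a config (independent of the fusion list
    and of read emission, so fusion specs can be chosen from the plan)."""
    rng = np.random.default_rng([config.seed, 101])
    n_chroms = len(config.chrom_lengths)
    total = sum(config.chrom_lengths)
    per_chrom = [max(1, round(config.n_genes * L / total)) for L in config.chrom_lengths]
    while sum(per_chrom) > config.n_genes:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < config.n_genes:
        per_chrom[int(np.argmin(per_chrom))] += 1

    genes: dict[str, GeneModel] = {}
    gi = 0
    for ci, clen in enumerate(config.chrom_lengths):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        slot = clen // n
        for j in range(n):
            gi += 1
            symbol = f"GENE{gi:02d}"
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
            in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                                   max(n_ex - 1, 0))
            start = j * slot + int(rng.integers(1000, max(slot // 4, 2000)))
            exons = []
            pos = start
            for e in range(n_ex):
                exons.append((pos, pos + int(ex_lens[e]) - 1))
                pos = exons[-1][1] + 1 + (int(in_lens[e]) if e < n_ex - 1 else 0)
            strand = "+" if rng.random() < 0.5 else "-"
            spliced_len = int(ex_lens.sum())
            # CDS bounds in transcript coordinates: start a little inside the
            # transcript, length a multiple of 3 ending before the 3' end
            c0 = 31
            c1 = spliced_len - 30
            c1 -= (c1 - c0 + 1) % 3
            g0 = transcript_to_genomic_static(exons, strand, c0)
            g1 = transcript_to_genomic_static(exons, strand, c1)
            genes[symbol] = GeneModel(
                name=f"NM_{gi:06d}", symbol=symbol, chrom=chrom, strand=strand,
                tx_start=exons[0][0], tx_end=exons[-1][1],
                cds_start=min(g0, g1), cds_end=max(g0, g1), exons=exons,
            )
    return genes


def transcript_to_genomic_static(exons: list[tuple[int, int]], strand: str, tpos: int) -> int:
    order = exons if strand == "+" else list(reversed(exons))
    t = 0
    for s, e in order:
        length = e - s + 1
        if tpos <= t + length:
            off = tpos - t - 1
            return s + off if strand == "+" else e - off
        t += length
    raise ValueError("transcript position beyond spliced length")


def _build_genome(config: SimConfig, genes: dict[str, GeneModel]) -> Genome:
    rng = np.random.default_rng([config.seed, 202])
    seqs = {f"chr{i + 1}": _random_seq(rng, L) for i, L in enumerate(config.chrom_lengths)}
    return Genome(seqs)


def _build_blacklist(config: SimConfig) -> dict[str, str]:
    rng = np.random.default_rng([config.seed, 303])
    return {
        "rRNA_like_1": _random_seq(rng, 1800),
        "rRNA_like_2": _random_seq(rng, 1500),
        "PhiX_like": _random_seq(rng, 1200),
    }


# ---------------------------------------------------------------------------
# Fusion construction
# ---------------------------------------------------------------------------

def _exon_boundary_positions(gene: GeneModel, ordinal: int) -> tuple[int, int]:
    """(transcription-order exon start pos, exon end pos) in genomic coords,
    where 'start'/'end' are 5'/3' in the transcription direction."""
    order = _tx_exons(gene)
    if not (1 <= ordinal <= len(order)):
        raise ConfigError(f"{gene.symbol}: exon ordinal {ordinal} out of range")
    s, e = order[ordinal - 1]
    return (s, e) if gene.strand == "+" else (e, s)


def fusion_junction_of(genes: dict[str, GeneModel], spec: FusionSpec) -> Junction:
    for sym in (spec.donor_gene, spec.acceptor_gene):
        if sym not in genes:
            raise ConfigError(f"fusion references unknown gene {sym!r}")
    gd = genes[spec.donor_gene]
    ga = genes[spec.acceptor_gene]
    _, d_end = _exon_boundary_positions(gd, spec.donor_exon)
    a_start, _ = _exon_boundary_positions(ga, spec.acceptor_exon)
    return Junction(
        donor=GenomePosition(gd.chrom, d_end, gd.strand),
        acceptor=GenomePosition(ga.chrom, a_start, ga.strand),
    )


def build_fusion_mrna(genome: Genome, genes: dict[str, GeneModel], spec: FusionSpec
                      ) -> tuple[str, int, Junction]:
    """(fusion mRNA sequence, length of the donor-preserved part, junction)."""
    j = fusion_junction_of(genes, spec)
    gd, ga = genes[spec.donor_gene], genes[spec.acceptor_gene]
    t_d = genomic_to_transcript(gd, j.donor.pos)
    t_a = genomic_to_transcript(ga, j.acceptor.pos)
    assert t_d is not None and t_a is not None
    donor_part = spliced_sequence(genome, gd)[:t_d]
    acceptor_part = spliced_sequence(genome, ga)[t_a - 1:]
    return donor_part + acceptor_part, t_d, j


def _set_stranded_base(genome: Genome, chrom: str, pos: int, strand: str, base: str) -> None:
    seq = genome.sequences[chrom]
    top = base if strand == "+" else reverse_complement(base)
    genome.sequences[chrom] = seq[: pos - 1] + top + seq[pos:]


def _remove_junction_microhomology(genome: Genome, genes: dict[str, GeneModel],
                                   spec: FusionSpec) -> None:
    """Edit discarded-side bases so the planted junction is coordinate-exact.

    If the donor's next (discarded) transcript base equals the acceptor's first
    preserved base, a junction read aligns equally well one base to the right —
    so that discarded base is changed; symmetrically for the acceptor's
    previous discarded base versus the donor's last preserved base."""
    j = fusion_junction_of(genes, spec)  # validates gene/exon references
    gd, ga = genes[spec.donor_gene], genes[spec.acceptor_gene]
    acc_first = genome.fetch(ga.chrom, j.acceptor.pos, j.acceptor.pos, ga.strand)
    don_last = genome.fetch(gd.chrom, j.donor.pos, j.donor.pos, gd.strand)
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    # a split read extends along the GENOME, so the bases that create
    # coordinate ambiguity are the genomic (intronic) neighbours of the
    # junction, in each gene's transcription direction
    p = j.donor.pos + (1 if gd.strand == "+" else -1)
    if 1 <= p <= genome.length(gd.chrom):
        cur = genome.fetch(gd.chrom, p, p, gd.strand)
        if cur == acc_first:
            _set_stranded_base(genome, gd.chrom, p, gd.strand, alt[cur])
    q = j.acceptor.pos - (1 if ga.strand == "+" else -1)
    if 1 <= q <= genome.length(ga.chrom):
        cur = genome.fetch(ga.chrom, q, q, ga.strand)
        if cur == don_last:
            _set_stranded_base(genome, ga.chrom, q, ga.strand, alt[cur])


def _in_frame(genes: dict[str, GeneModel], spec: FusionSpec) -> bool:
    """Phase arithmetic on the planned CDS bounds (truth-set annotation)."""
    gd, ga = genes[spec.donor_gene], genes[spec.acceptor_gene]
    j = fusion_junction_of(genes, spec)
    t_d = genomic_to_transcript(gd, j.donor.pos)
    t_a = genomic_to_transcript(ga, j.acceptor.pos)
    if not (gd.coding and ga.coding):
        return False
    cd0 = genomic_to_transcript(gd, gd.cds_start if gd.strand == "+" else gd.cds_end)
    cd1 = genomic_to_transcript(gd, gd.cds_end if gd.strand == "+" else gd.cds_start)
    ca0 = genomic_to_transcript(ga, ga.cds_start if ga.strand == "+" else ga.cds_end)
    ca1 = genomic_to_transcript(ga, ga.cds_end if ga.strand == "+" else ga.cds_start)
    if not (cd0 <= t_d <= cd1 and ca0 <= t_a <= ca1):
        return False
    return (t_d - cd0 + 1) % 3 == (t_a - ca0) % 3


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

@dataclass
class _Molecule:
    seq: str
    weight: float
    intronic: bool = False  # marks unspliced molecules (for calibration tests)


def emit_reads(pool: list[_Molecule], n: int, config: SimConfig,
               rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Draw ``n`` reads from a molecule pool.

    A fragment start is uniform on its molecule and the fragment length
    log-normal; fragments shorter than the read length (including pieces
    running off the 3' end) are dropped and redrawn.  Each read is the first
    ``read_len`` bases of its fragment, on the sense strand (directional
    protocol).  Returns (sequence, pool index, start offset) triples.
    """
    if not pool:
        raise ValueError("empty molecule pool")
    L = config.read_len
    if max(len(m.seq) for m in pool) < L:
        raise ValueError("every pool molecule is shorter than the read length")
    lens = np.array([len(m.seq) for m in pool], dtype=float)
    w = np.array([m.weight for m in pool], dtype=float) * lens
    p = w / w.sum()
    out: list[tuple[str, int, int]] = []
    while len(out) < n:
        batch = max(256, int((n - len(out)) * 1.6))
        idx = rng.choice(len(pool), size=batch, p=p)
        frag = fragment_lengths(batch, config.fragment_median_bp, rng,
                                sigma=config.fragment_sigma)
        starts = (rng.random(batch) * lens[idx]).astype(int)
        for i in range(batch):
            if len(out) >= n:
                break
            m = pool[int(idx[i])]
            s = int(starts[i])
            piece = m.seq[s : s + int(frag[i])]
            if len(piece) < L:
                continue
            out.append((piece[:L], int(idx[i]), s))
    return out


# ---------------------------------------------------------------------------
# Cohort builder
# ---------------------------------------------------------------------------

def build_toy_cohort(config: SimConfig, outdir: str) -> CohortFiles:
    """Write genome FASTA, refGene, blacklist FASTA, per-sample FASTQ and the
    truth TSV for a simulated cohort.  Deterministic given ``config.seed``."""
    os.makedirs(outdir, exist_ok=True)
    genes = plan_genes(config)
    genome = _build_genome(config, genes)
    samples = config.sample_names()
    for spec in config.fusions:
        for s in spec.samples:
            if s not in samples:
                raise ConfigError(f"fusion references unknown sample {s!r}")
        _remove_junction_microhomology(genome, genes, spec)

    blacklist = _build_blacklist(config)
    fusion_data = [(spec, *build_fusion_mrna(genome, genes, spec)) for spec in config.fusions]

    # cohort-level baseline expression per gene, with per-sample noise
    rng_expr = np.random.default_rng([config.seed, 404])
    base_w = {sym: float(np.exp(0.6 * rng_expr.standard_normal())) for sym in genes}

    truth: list[TruthRecord] = []
    fastqs: dict[str, str] = {}
    for si, sample in enumerate(samples):
        rng = np.random.default_rng([config.seed, 1000 + si])
        pool: list[_Molecule] = []
        p = config.premrna_fraction
        for sym, gene in genes.items():
            w = base_w[sym] * float(np.exp(0.25 * rng.standard_normal()))
            pool.append(_Molecule(spliced_sequence(genome, gene), w * (1 - p)))
            pre = genome.fetch(gene.chrom, gene.tx_start, gene.tx_end, gene.strand)
            pool.append(_Molecule(pre, w * p, intronic=True))
        planted: list[str] = []
        for spec, mrna, t_d, junction in fusion_data:
            if sample not in spec.samples:
                continue
            w_add = spec.expression_fold * base_w[spec.acceptor_gene] * (1 - p)
            pool.append(_Molecule(mrna[:t_d], w_add))       # donor-preserved boost
            pool.append(_Molecule(mrna[t_d:], w_add))       # acceptor-preserved boost
            # exact junction-spanning reads at distinct offsets (>=20 bp/side)
            n_t = spec.junction_reads_target
            offs = [20 + (3 * i) % 11 for i in range(n_t)]
            for off in offs:
                planted.append(mrna[t_d - off : t_d - off + config.read_len])
            truth.append(TruthRecord(format_junction_string(junction), sample,
                                     n_t, _in_frame(genes, spec)))
        n_cont = int(round(config.depth * config.contaminant_fraction))
        n_background = max(config.depth - n_cont - len(planted), 0)
        seqs = [s for s, _, _ in emit_reads(pool, n_background, config, rng)]
        bl_seqs = list(blacklist.values())
        for _ in range(n_cont):
            src = bl_seqs[int(rng.integers(len(bl_seqs)))]
            s0 = int(rng.integers(0, len(src) - config.read_len + 1))
            seqs.append(src[s0 : s0 + config.read_len])
        seqs.extend(planted)
        order = rng.permutation(len(seqs))
        qual_line = chr(config.quality + 33) * config.read_len
        fq_path = os.path.join(outdir, f"{sample}.fastq")
        with open(fq_path, "w") as fh:
            for ri, oi in enumerate(order):
                fh.write(f"@{sample}_r{ri:06d}\n{seqs[int(oi)]}\n+\n{qual_line}\n")
        fastqs[sample] = fq_path

    genome_fa = os.path.join(outdir, "genome.fa")
    genome.to_fasta(genome_fa)
    refgene = os.path.join(outdir, "refGene.txt")
    write_refgene(genes.values(), refgene)
    blacklist_fa = os.path.join(outdir, "blacklist.fa")
    with open(blacklist_fa, "w") as fh:
        for name, seq in blacklist.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    truth_tsv = os.path.join(outdir, "truth.tsv")
    with open(truth_tsv, "w") as fh:
        fh.write("junction\tsample\tn_planted_junction_reads\tin_frame\n")
        for rec in truth:
            fh.write(f"{rec.junction}\t{rec.sample}\t{rec.n_planted_junction_reads}"
                     f"\t{int(rec.in_frame)}\n")
    return CohortFiles(genome_fa, refgene, blacklist_fa, fastqs, truth_tsv,
                       genome, genes, truth)


# ---------------------------------------------------------------------------
# Standard demonstration cohort
# ---------------------------------------------------------------------------

def default_demo_config(seed: int = 1, n_samples: int = 12,
                        junction_reads: int = 4) -> SimConfig:
    """A 12-sample cohort with six implanted fusions covering the candidacy
    classes: two inter-chromosomal, two same-chromosome co-directional pairs
    more than 1 Mb apart, one opposite-strand pair, and one recurrent
    inter-chromosomal fusion carried by two samples."""
    config = SimConfig(seed=seed, n_samples=n_samples)
    genes = plan_genes(config)
    syms = list(genes)
    used: set[str] = set()

    def take(pred) -> tuple[str, str]:
        for a in syms:
            if a in used:
                continue
            for b in syms:
                if b in used or b == a:
                    continue
                if pred(genes[a], genes[b]):
                    used.update((a, b))
                    return a, b
        raise ConfigError("gene plan cannot satisfy the demo fusion classes")

    def inter(a: GeneModel, b: GeneModel) -> bool:
        return a.chrom != b.chrom

    def far_codir(a: GeneModel, b: GeneModel) -> bool:
        return (a.chrom == b.chrom and a.strand == b.strand
                and abs(a.tx_start - b.tx_start) >= 1_050_000)

    def opp(a: GeneModel, b: GeneModel) -> bool:
        return a.chrom == b.chrom and a.strand != b.strand

    samples = config.sample_names()
    pairs = [take(inter), take(inter), take(far_codir), take(far_codir), take(opp),
             take(inter)]
    carriers = [(samples[0],), (samples[1],), (samples[2],), (samples[3],),
                (samples[4],), (samples[5], samples[6])]
    fusions = tuple(
        FusionSpec(d, 2, a, 2, samples=c, junction_reads_target=junction_reads)
        for (d, a), c in zip(pairs, carriers)
    )
    return replace(config, fusions=fusions)
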