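"""Read filters, the seed-and-extend aligner, the retest filter and counting."""

import numpy as np
import pytest

from gfuse.align import (FeatureIndex, GeneTable, Read, SegmentAlignment, SeqIndex,
                         abundance_filter, count_features, encode, junction_of,
                         load_fastq, map_read, quality_filter, read_sam,
                         retest_distant_read, revcomp_codes, write_sam)
from gfuse.genome_model import Genome, reverse_complement

from conftest import make_gene, make_read, random_seq


def brute_force_best_local(genome: Genome, seq: str):
    """All-positions, both-strands contiguous alignment oracle.

    Returns (best match count, list of (chrom, start1, strand) placements).
    """
    L = len(seq)
    best, placements = -1, []
    for strand in "+-":
        q = encode(seq if strand == "+" else reverse_complement(seq))
        for chrom, s in genome.sequences.items():
            g = encode(s)
            n = len(g) - L + 1
            if n <= 0:
                continue
            scores = np.zeros(n, dtype=np.int32)
            for i in range(L):
                scores += g[i: i + n] == q[i]
            m = int(scores.max())
            if m > best:
                best, placements = m, []
            if m == best:
                for pos in np.nonzero(scores == m)[0]:
                    placements.append((chrom, int(pos) + 1, strand))
    return best, placements


class TestQualityFilter:
    def test_all_high_passes(self):
        assert quality_filter(make_read("A" * 50, q=30))

    def test_threshold_boundary(self):
        quals = np.array([20] * 15 + [10] * 35, dtype=np.uint8)
        assert quality_filter(Read("r", "A" * 50, quals))
        quals = np.array([20] * 14 + [10] * 36, dtype=np.uint8)
        assert not quality_filter(Read("r", "A" * 50, quals))


class TestAbundanceFilter:
    @pytest.fixture(scope="class")
    def blacklist(self):
        seq = random_seq(np.random.default_rng(42), 1000)
        return seq, SeqIndex({"rRNA_like": seq}, k=12)

    def test_exact_substring_dropped(self, blacklist):
        seq, idx = blacklist
        assert not abundance_filter(make_read(seq[100:150]), idx)

    def test_unrelated_read_kept(self, blacklist):
        _, idx = blacklist
        read = make_read(random_seq(np.random.default_rng(77), 50))
        assert abundance_filter(read, idx)

    def test_six_mismatches_kept(self, blacklist):
        seq, idx = blacklist
        s = list(seq[200:250])
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in (44, 45, 46, 47, 48, 49):
            s[i] = flip[s[i]]
        read = make_read("".join(s))
        # brute-force oracle: best blacklist match is 44/50, below the 45 cut
        best, _ = brute_force_best_local(Genome({"b": seq}), read.seq)
        assert best == 44
        assert abundance_filter(read, idx)


class TestMapRead:
    @pytest.fixture(scope="class")
    def index(self, tiny_genome):
        return SeqIndex(tiny_genome.sequences, k=15)

    def test_exact_substring_maps_local_unique(self, tiny_genome, index):
        seq = tiny_genome.fetch("chr1", 2001, 2050)
        (aln,) = map_read(make_read(seq), index)
        assert aln.kind == "local" and aln.unique
        seg = aln.segments[0]
        assert (seg.chrom, seg.gstart, seg.gend, seg.strand) == ("chr1", 2001, 2050, "+")

    def test_minus_strand_read_maps_reverse(self, tiny_genome, index):
        seq = tiny_genome.fetch("chr2", 501, 550, "-")
        (aln,) = map_read(make_read(seq), index)
        seg = aln.segments[0]
        assert (seg.chrom, seg.gstart, seg.gend, seg.strand) == ("chr2", 501, 550, "-")

    def test_duplicated_locus_not_unique(self):
        rng = np.random.default_rng(5)
        core = random_seq(rng, 60)
        genome = Genome({"c": random_seq(rng, 500) + core + random_seq(rng, 500)
                         + core + random_seq(rng, 300)})
        idx = SeqIndex(genome.sequences, k=15)
        (aln,) = map_read(make_read(core[5:55]), idx)
        assert not aln.unique

    def test_random_foreign_read_unmapped(self, index):
        read = make_read(random_seq(np.random.default_rng(999), 50))
        assert map_read(read, index) == []

    @pytest.mark.parametrize("strand1,strand2", [("+", "+"), ("+", "-"),
                                                 ("-", "+"), ("-", "-")])
    def test_planted_chimera_reported_at_exact_junction(self, tiny_genome, index,
                                                        strand1, strand2):
        """25+25 chimeric reads across chromosomes come back distant_spliced
        with donor = last base of segment 1, acceptor = first base of
        segment 2, for every strand combination."""
        rng = np.random.default_rng(17 + 2 * (strand1 == "-") + (strand2 == "-"))
        found = 0
        for _ in range(20):
            p1 = int(rng.integers(100, 9000))
            p2 = int(rng.integers(100, 7000))
            if strand1 == "+":
                pre = tiny_genome.fetch("chr1", p1 - 24, p1, "+")
                nxt = tiny_genome.fetch("chr1", p1 + 1, p1 + 1, "+")
            else:
                pre = tiny_genome.fetch("chr1", p1, p1 + 24, "-")
                nxt = tiny_genome.fetch("chr1", p1 - 1, p1 - 1, "-")
            if strand2 == "+":
                suf = tiny_genome.fetch("chr2", p2, p2 + 24, "+")
                prv = tiny_genome.fetch("chr2", p2 - 1, p2 - 1, "+")
            else:
                suf = tiny_genome.fetch("chr2", p2 - 24, p2, "-")
                prv = tiny_genome.fetch("chr2", p2 + 1, p2 + 1, "-")
            # skip microhomologous flanks: there the junction is genuinely
            # ambiguous at sequence level
            if nxt == suf[0] or prv == pre[-1]:
                continue
            (aln,) = map_read(make_read(pre + suf), index)
            assert aln.kind == "distant_spliced"
            dchrom, dpos, dstrand, achrom, apos, astrand = junction_of(aln)
            assert (dchrom, dpos, dstrand) == ("chr1", p1, strand1)
            assert (achrom, apos, astrand) == ("chr2", p2, strand2)
            found += 1
        assert found >= 10

    def test_local_splice_vs_distant_classification(self, tiny_genome, index):
        # same chrom, same strand, forward order, short gap -> local_spliced
        a = tiny_genome.fetch("chr1", 1001, 1025)
        b = tiny_genome.fetch("chr1", 3001, 3025)
        (aln,) = map_read(make_read(a + b), index)
        assert aln.kind == "local_spliced"
        # reversed order (acceptor genomically upstream) -> distant
        (aln,) = map_read(make_read(b + a), index)
        assert aln.kind == "distant_spliced"

    def test_oracle_equivalence_on_random_reads(self, tiny_genome, index):
        """Seed-and-extend agrees with the brute-force all-positions oracle on
        best score and location for 200 random (possibly mutated) reads."""
        rng = np.random.default_rng(2024)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        checked = 0
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            n = len(tiny_genome.sequences[chrom])
            pos = int(rng.integers(1, n - 50))
            strand = "+" if rng.random() < 0.5 else "-"
            s = list(tiny_genome.fetch(chrom, pos, pos + 49, strand))
            # ≤2 mutations: a 50-mer then always keeps one clean seed-length run
            for q in rng.choice(50, size=int(rng.integers(0, 3)), replace=False):
                s[q] = flip[s[q]]
            seq = "".join(s)
            best, placements = brute_force_best_local(tiny_genome, seq)
            alns = map_read(make_read(seq), index)
            assert alns, f"oracle found {best} matches but aligner nothing"
            aln = alns[0]
            if aln.kind != "local":
                continue  # a split placement outscored the contiguous one
            seg = aln.segments[0]
            assert 50 - len(seg.mismatches) == best
            assert (seg.chrom, seg.gstart, seg.strand) in placements
            assert aln.unique == (len(placements) == 1)
            checked += 1
        assert checked >= 195


class TestRetest:
    @pytest.fixture(scope="class")
    def index(self, tiny_genome):
        return SeqIndex(tiny_genome.sequences, k=15)

    def _mutated(self, tiny_genome, n_mm):
        # mutate tail bases so they also miss the ±1-shifted diagonals the
        # 1 bp gap allowance can reach — the matched count is then exact
        ref = tiny_genome.fetch("chr1", 5000, 5051)  # one spare base each side
        s = list(ref[1:51])
        for i in range(50 - n_mm, 50):
            neighbours = {ref[i], ref[i + 1], ref[i + 2]}
            s[i] = next(b for b in "ACGT" if b not in neighbours)
        return make_read("".join(s))

    def test_discard_at_44_matches(self, tiny_genome, index):
        assert retest_distant_read(self._mutated(tiny_genome, 6), index) is False

    def test_keep_at_43_matches(self, tiny_genome, index):
        assert retest_distant_read(self._mutated(tiny_genome, 7), index) is True

    def test_gapped_pseudochimera_discarded(self, tiny_genome, index):
        # 49 genomic bases with one deleted -> 46 matches + 1 bp gap after
        # three extra mismatches: still >= 44, so discard
        raw = tiny_genome.fetch("chr1", 6001, 6051)
        seq = list(raw[:25] + raw[26:])  # 50 bases, 1 bp deletion vs genome
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in (47, 48, 49):
            seq[i] = flip[seq[i]]
        assert retest_distant_read(make_read("".join(seq)), index) is False

    def test_genuine_chimera_kept(self, tiny_genome, index):
        seq = tiny_genome.fetch("chr1", 2001, 2025) + \
              tiny_genome.fetch("chr2", 4001, 4025)
        best, _ = brute_force_best_local(tiny_genome, seq)
        assert best < 44  # brute-force confirms no single locus explains it
        assert retest_distant_read(make_read(seq), index) is True

    def test_pseudochimera_removal_rate(self, tiny_genome, index):
        """Contiguous genomic 50-mers artificially split in two realign
        locally with >= 44 matches: the retest removes every one."""
        rng = np.random.default_rng(31)
        removed = 0
        for _ in range(200):
            pos = int(rng.integers(1, 9_900))
            seq = tiny_genome.fetch("chr1", pos, pos + 49)
            if not retest_distant_read(make_read(seq), index):
                removed += 1
        assert removed >= 198  # >= 99 %


class TestCountFeatures:
    @pytest.fixture(scope="class")
    def findex(self):
        g = make_gene("G", "chr1", "+", [(1001, 1200), (1501, 1700)])
        return FeatureIndex({"G": g})

    def _local(self, rid, chrom, start, end, unique=True, q0=0):
        from gfuse.align import Segment
        seg = Segment(chrom, "+", start, end, q0, q0 + (end - start))
        return SegmentAlignment(rid, (seg,), "local", unique, end - start + 1)

    def test_read_inside_exon(self, findex):
        counts, total = count_features([self._local("r", "chr1", 1050, 1099)], findex)
        assert counts == {"G|exon1": 50} and total == 50

    def test_exon_intron_straddle(self, findex):
        counts, _ = count_features([self._local("r", "chr1", 1171, 1220)], findex)
        assert counts == {"G|exon1": 30, "G|intron1": 20}

    def test_non_unique_contributes_nothing(self, findex):
        counts, total = count_features(
            [self._local("r", "chr1", 1050, 1099, unique=False)], findex)
        assert counts == {} and total == 0

    def test_counted_bases_bounded_by_aligned_bases(self, findex, rng):
        alns = [self._local(f"r{i}", "chr1", int(p), int(p) + 49)
                for i, p in enumerate(rng.integers(900, 1800, 50))]
        counts, total = count_features(alns, findex)
        assert sum(counts.values()) <= total == 50 * 50


class TestSamRoundTrip:
    def test_gene_table_identical_after_sam_cycle(self, tiny_genome, tmp_path):
        gene = make_gene("G", "chr1", "+", [(2001, 2300), (2601, 2900)])
        gene2 = make_gene("H", "chr2", "-", [(1001, 1300), (1601, 1900)])
        findex = FeatureIndex({"G": gene, "H": gene2})
        index = SeqIndex(tiny_genome.sequences, k=15)
        rng = np.random.default_rng(8)
        reads, alns = [], {}
        for i in range(60):
            if i % 2 == 0:
                pos = int(rng.integers(1950, 2900))
                seq = tiny_genome.fetch("chr1", pos, pos + 49)
            else:
                pos = int(rng.integers(950, 1900))
                seq = tiny_genome.fetch("chr2", pos, pos + 49, "-")
            r = make_read(seq, rid=f"r{i:03d}")
            reads.append(r)
            alns[r.id] = map_read(r, index)
        flat = [a[0] for a in alns.values() if a]
        counts_direct, total_direct = count_features(flat, findex)

        sam = tmp_path / "x.sam"
        write_sam(str(sam), tiny_genome, reads, alns)
        back, unmapped = read_sam(str(sam))
        flat_back = [a[0] for a in back.values()]
        counts_back, total_back = count_features(flat_back, findex)
        assert counts_back == counts_direct
        assert total_back == total_direct
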