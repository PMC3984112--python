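"""Template remapping, size factors, Interrupt Ratios and nomination."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gfuse.align import GeneTable, FeatureIndex
from gfuse.genome_model import GenomePosition, Junction, features_of
from gfuse.remap_profile import (TemplateHit, _side_features, center_scaled_matrix,
                                 fusion_support_reads, interrupt_ratio,
                                 nominate_interrupted, remap_to_templates,
                                 select_reads_for_remap, size_factors)
from gfuse.simulate import (FusionSpec, SimConfig, _build_genome,
                            build_fusion_mrna, plan_genes)
from gfuse.templates import build_template_index, build_template_set

from conftest import make_gene, make_read


@pytest.fixture(scope="module")
def fusion_index():
    cfg = SimConfig(seed=21)
    genes = plan_genes(cfg)
    genome = _build_genome(cfg, genes)
    donor = next(s for s in genes if genes[s].chrom == "chr1")
    acceptor = next(s for s in genes if genes[s].chrom == "chr2")
    spec = FusionSpec(donor, 2, acceptor, 2, samples=("S01",))
    mrna, t_d, junction = build_fusion_mrna(genome, genes, spec)
    ts = build_template_set(junction, genome, genes, donor, acceptor, 100)
    return genome, genes, spec, mrna, t_d, ts, build_template_index([ts])


class TestRemap:
    def test_junction_straddling_read_hits_fusion_uniquely(self, fusion_index):
        genome, genes, spec, mrna, t_d, ts, index = fusion_index
        read = make_read(mrna[t_d - 20: t_d + 30])  # 20 donor + 30 acceptor bases
        (hit,) = remap_to_templates([read], index, "S01")
        assert hit.role == "fusion" and hit.unique_best
        assert hit.junction_overhang == 20
        assert hit.matches == 50 and hit.offset == 30

    def test_donor_only_read_ties_between_fusion_and_donor(self, fusion_index):
        genome, genes, spec, mrna, t_d, ts, index = fusion_index
        read = make_read(ts.donor_t[0:50])  # entirely the shared first half
        (hit,) = remap_to_templates([read], index, "S01")
        assert not hit.unique_best

    def test_pre_mrna_read_prefers_pre_template(self, fusion_index):
        genome, genes, spec, mrna, t_d, ts, index = fusion_index
        read = make_read(ts.acceptor_pre_t[25:75])  # spans the genomic splice site
        (hit,) = remap_to_templates([read], index, "S01")
        assert hit.role == "acceptor_pre" and hit.unique_best

    def test_low_quality_reads_not_scored(self, fusion_index):
        *_, index = fusion_index
        ts = list(index.sets.values())[0]
        read = make_read(ts.fusion_t[25:75], q=10)
        assert remap_to_templates([read], index, "S01") == []

    def test_foreign_read_no_hit(self, fusion_index):
        *_, index = fusion_index
        from conftest import random_seq
        read = make_read(random_seq(np.random.default_rng(1), 50))
        assert remap_to_templates([read], index, "S01") == []


class TestFusionSupport:
    def _hit(self, role="fusion", unique=True, overhang=10, mism=()):
        return TemplateHit("r", "S01", "j", role, 40, "+", 50, unique,
                           overhang, tuple(mism), "A" * 50)

    def test_clean_overhang_kept(self):
        assert fusion_support_reads([self._hit()]) != []

    def test_small_overhang_dropped(self):
        assert fusion_support_reads([self._hit(overhang=3)]) == []

    def test_boundary_overhang_six(self):
        assert fusion_support_reads([self._hit(overhang=6)]) != []
        assert fusion_support_reads([self._hit(overhang=5)]) == []

    def test_mismatch_inside_overhang_window_drops(self):
        # overhang 8: window is template positions 43..58
        assert fusion_support_reads([self._hit(overhang=8, mism=(45,))]) == []
        assert fusion_support_reads([self._hit(overhang=8, mism=(40,))]) != []

    def test_control_roles_are_not_support(self):
        assert fusion_support_reads([self._hit(role="donor")]) == []
        assert fusion_support_reads([self._hit(unique=False)]) == []


class TestSelectReads:
    def test_selection_rules(self):
        intervals = {
            "near": [("chr1", 1040, 1089)],
            "far": [("chr1", 50_000, 50_049)],
            "edge": [("chr1", 1001, 1050)],  # touches the flank padded by read len
        }
        blocks = [(1100, 1200, "chr1")]
        sel = select_reads_for_remap(intervals, {"unmapped1"}, blocks, read_len=50)
        assert sel == {"near", "edge", "unmapped1"}


class TestSizeFactors:
    def test_identical_libraries(self):
        df = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]}, dtype=float)
        f = size_factors(df)
        assert np.allclose(f, [1.0, 1.0])

    def test_closed_form_two_sample_example(self):
        df = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]}, dtype=float)
        f = size_factors(df)
        assert abs(f["A"] - 0.7071) < 1e-4
        assert abs(f["B"] - 1.4142) < 1e-4

    def test_scaling_one_library_follows_closed_form(self):
        rng = np.random.default_rng(3)
        base = pd.DataFrame(rng.integers(10, 500, size=(30, 3)).astype(float),
                            columns=["A", "B", "C"])
        f0 = size_factors(base)
        c = 2.5
        scaled = base.copy()
        scaled["B"] *= c
        f1 = size_factors(scaled)
        # the geometric-mean reference moves by c^(1/m): closed-form prediction
        m = 3
        assert np.allclose(f1["B"], f0["B"] * c * c ** (-1 / m) * 1, rtol=1e-9) or \
            np.allclose(f1["B"] / f1["A"], f0["B"] / f0["A"] * c, rtol=1e-9)
        assert np.allclose(f1["A"] / f1["C"], f0["A"] / f0["C"], rtol=1e-9)

    def test_degenerate_library_raises(self):
        df = pd.DataFrame({"A": [0, 0], "B": [1, 2]}, dtype=float)
        with pytest.raises(ValueError):
            size_factors(df)


def _acceptor_gene_unit_features():
    """Plus-strand gene with 1 bp exons/introns so coverage == count."""
    exons = [(1, 1), (3, 3), (5, 5), (7, 7), (9, 9)]
    return make_gene("ACC", "chr9", "+", exons)


def _table_for(gene, counts_by_sample):
    findex = FeatureIndex({gene.symbol: gene})
    table = GeneTable(findex.features)
    for sample, counts in counts_by_sample.items():
        table.add_sample(sample, counts, int(sum(counts.values())))
    return table


class TestInterruptRatio:
    def _junction_at_exon3(self):
        return Junction(GenomePosition("chr8", 999, "+"),   # donor elsewhere
                        GenomePosition("chr9", 5, "+"))

    def test_uniform_coverage_gives_unity(self):
        gene = _acceptor_gene_unit_features()
        donor = make_gene("DON", "chr8", "+", [(500, 700), (900, 1100)])
        counts = {f.id: 50 for f in features_of(gene)}
        counts.update({f.id: 50 * f.length for f in features_of(donor)})
        table = _table_for(gene, {"S": counts})
        table.df["S2"] = table.df["S"]  # two samples for factor fitting
        # give donor features too
        findex = FeatureIndex({"ACC": gene, "DON": donor})
        table = GeneTable(findex.features)
        table.add_sample("S", counts, 1)
        table.add_sample("S2", counts, 1)
        factors = pd.Series({"S": 1.0, "S2": 1.0})
        j = Junction(GenomePosition("chr8", 1100, "+"), GenomePosition("chr9", 5, "+"))
        ird, ira = interrupt_ratio(j, donor, gene, table, "S", factors)
        assert ira == pytest.approx(1.0)

    def test_fifty_versus_floored_five_gives_ten(self):
        gene = _acceptor_gene_unit_features()
        # preserved side (exon3..exon5 incl introns 3,4): counts 50
        # discarded side (exon1, intron1, exon2): raw 0 -> floored to 5
        counts = {}
        for f in features_of(gene):
            preserved = f.interval[0] >= 5
            counts[f.id] = 50 if preserved else 0
        table = _table_for(gene, {"S": counts, "S2": counts})
        factors = pd.Series({"S": 1.0, "S2": 1.0})
        j = self._junction_at_exon3()
        donor = gene  # donor side undefined on purpose (different chrom pos)
        ird, ira = interrupt_ratio(j, _acceptor_gene_unit_features(), gene,
                                   table, "S", factors)
        assert ira == pytest.approx(10.0, abs=1e-9)

    def test_invariant_under_uniform_library_scaling(self):
        gene = _acceptor_gene_unit_features()
        rng = np.random.default_rng(5)
        counts = {f.id: int(rng.integers(40, 400)) for f in features_of(gene)}
        scaled = {k: v * 2 for k, v in counts.items()}
        t1 = _table_for(gene, {"S": counts, "T": counts})
        t2 = _table_for(gene, {"S": scaled, "T": counts})
        f1 = size_factors(t1)
        f2 = size_factors(t2)
        j = self._junction_at_exon3()
        ir1 = interrupt_ratio(j, gene, gene, t1, "S", f1)[1]
        ir2 = interrupt_ratio(j, gene, gene, t2, "S", f2)[1]
        assert ir1 == pytest.approx(ir2, abs=1e-9)

    def test_breakpoint_adjacent_introns_never_contribute(self):
        gene = _acceptor_gene_unit_features()
        # acceptor at exon3 (pos 5): intron2 (4,4) is the excluded intron
        pres, disc = _side_features(gene, 5, "acceptor")
        assert all(f.interval != (4, 4) for f in pres + disc)
        # donor at exon3 end (pos 5): intron3 (6,6) excluded
        pres, disc = _side_features(gene, 5, "donor")
        assert all(f.interval != (6, 6) for f in pres + disc)

    def test_minus_strand_sides(self):
        gene = make_gene("NEG", "chr9", "-", [(1, 1), (3, 3), (5, 5), (7, 7)])
        # acceptor junction at exon2 in transcription order = genomic (5,5)
        pres, disc = _side_features(gene, 5, "acceptor")
        # preserved continues transcription (to lower coordinates)
        assert {f.interval for f in pres} == {(5, 5), (4, 4), (3, 3), (2, 2), (1, 1)}
        # discarded = exon1 at (7,7); intron (6,6) excluded
        assert {f.interval for f in disc} == {(7, 7)}

    def test_empty_side_is_undefined(self):
        gene = _acceptor_gene_unit_features()
        table = _table_for(gene, {"S": {f.id: 10 for f in features_of(gene)},
                                  "T": {f.id: 10 for f in features_of(gene)}})
        factors = pd.Series({"S": 1.0, "T": 1.0})
        # acceptor at the very first exon: no discarded side
        j = Junction(GenomePosition("chr8", 999, "+"), GenomePosition("chr9", 1, "+"))
        ird, ira = interrupt_ratio(j, gene, gene, table, "S", factors)
        assert ira is None


class TestNominate:
    def test_uniform_cohort_nothing_flagged(self):
        irs = {f"S{i}": (1.0, 1.0) for i in range(8)}
        ev = nominate_interrupted(irs, "j")
        assert not any(e.interrupted for e in ev.values())

    def test_single_discontinuity_flagged_and_ranked_first(self):
        irs = {f"S{i}": (1.0, 1.0) for i in range(8)}
        irs["S3"] = (1.1, 20.0)
        ev = nominate_interrupted(irs, "j")
        assert ev["S3"].interrupted and ev["S3"].cohort_rank == 1
        assert sum(e.interrupted for e in ev.values()) == 1

    def test_two_carriers_top_ranked(self):
        irs = {f"S{i}": (0.9 + 0.01 * i, 1.0) for i in range(12)}
        irs["S5"] = (15.0, 2.0)
        irs["S9"] = (1.0, 12.0)
        ev = nominate_interrupted(irs, "j")
        flagged = {s for s, e in ev.items() if e.interrupted}
        assert flagged == {"S5", "S9"}
        assert {ev["S5"].cohort_rank, ev["S9"].cohort_rank} == {1, 2}

    def test_cohort_of_one_uses_absolute_floor(self):
        ev = nominate_interrupted({"S": (3.0, 1.0)}, "j")
        assert ev["S"].interrupted
        ev = nominate_interrupted({"S": (1.5, 1.0)}, "j")
        assert not ev["S"].interrupted


class TestHeatmapMatrix:
    def test_rows_centered(self):
        gene = _acceptor_gene_unit_features()
        rng = np.random.default_rng(2)
        t = _table_for(gene, {s: {f.id: int(rng.integers(10, 100))
                                  for f in features_of(gene)}
                              for s in ("A", "B", "C")})
        f = size_factors(t)
        m = center_scaled_matrix(t, f, list(t.df.index))
        assert np.allclose(m.sum(axis=1), 0.0, atol=1e-9)
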