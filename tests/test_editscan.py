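"""Mapping, pileups, editing-site calling, codon effects, line comparison."""

import random

import numpy as np
import pytest
from _oracles import CODON_TABLE_11

from plastiq import synthio
from plastiq.editscan import (Alignment, GenePileup, NaiveMapper,
                              annotate_codon_effect, build_pileup,
                              call_editing_sites, compare_editing, naive_map,
                              read_sam, write_sam)
from plastiq.genome import CircularGenome, Interval, revcomp
from plastiq.io import SeqRead
from plastiq.structure import GeneAnnotation


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestNaiveMapper:
    def test_error_free_reads_place_at_true_offset(self, small_plastome):
        _, genome, _, _ = small_plastome
        rng = np.random.default_rng(0)
        mapper = NaiveMapper(genome)
        for _ in range(40):
            pos = int(rng.integers(0, len(genome)))
            seq = genome.fetch(pos, pos + 120)
            flipped = rng.random() < 0.5
            aln = mapper.map_read(SeqRead("r", revcomp(seq) if flipped
                                          else seq))
            if aln.status == "unique":  # reads from inside the IR multi-map
                assert aln.pos == pos
                assert aln.seq == seq
                assert aln.strand == ("-" if flipped else "+")

    def test_ir_read_is_multi_placed(self, small_plastome):
        _, genome, _, truth = small_plastome
        ira = truth.regions["ira"]
        seq = genome.fetch(ira.start + 100, ira.start + 300)
        aln = NaiveMapper(genome).map_read(SeqRead("r", seq))
        assert aln.status == "multi"
        assert len(aln.placements) == 2

    def test_mapping_rate_with_one_percent_errors(self, small_plastome):
        _, genome, _, _ = small_plastome
        rng = np.random.default_rng(1)
        lsc_len = 5000
        mapper = NaiveMapper(genome)
        n_ok = 0
        n = 300
        for _ in range(n):
            pos = int(rng.integers(0, lsc_len - 150))
            seq = list(genome.fetch(pos, pos + 150))
            for i in range(len(seq)):
                if rng.random() < 0.01:
                    seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
            aln = mapper.map_read(SeqRead("r", "".join(seq)))
            n_ok += aln.status == "unique" and aln.pos == pos
        assert n_ok >= 0.99 * n

    def test_sam_round_trip(self, small_plastome, tmp_path):
        _, genome, _, _ = small_plastome
        reads = [SeqRead("a", genome.fetch(10, 130)),
                 SeqRead("b", revcomp(genome.fetch(500, 650))),
                 SeqRead("c", "ACGT" * 30)]
        alns = naive_map(reads, genome)
        path = tmp_path / "x.sam"
        write_sam(alns, genome, path)
        back = read_sam(path)
        assert [(a.read_id, a.pos, a.strand, a.status) for a in back] == \
            [(a.read_id, a.pos, a.strand, a.status) for a in alns]


def _uniform_genome(seq):
    return CircularGenome("g", seq)


class TestBuildPileup:
    def test_forward_gene_counts_edited_base(self):
        rng = np.random.default_rng(4)
        seq = _random_seq(rng, 300)
        seq = seq[:100] + "C" + seq[101:]
        g = _uniform_genome(seq)
        gene = GeneAnnotation("g1", "g1", "protein", "+", (Interval(60, 180),))
        # 60 identical reads carrying T over the reference C at position 100
        read_seq = seq[80:100] + "T" + seq[101:160]
        alns = [Alignment(f"r{i}", 80, "+", read_seq, 1, "unique")
                for i in range(60)]
        pu = build_pileup(alns, g, [gene])["g1"]
        cds_pos = 100 - 60 + 1
        assert pu.depth(cds_pos) == 60
        assert pu.base_count(cds_pos, "T") == 60
        assert pu.cds_seq[cds_pos - 1] == "C"

    def test_minus_strand_gene_complements_bases(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 300)
        seq = seq[:100] + "G" + seq[101:]  # sense-strand C on a minus gene
        g = _uniform_genome(seq)
        gene = GeneAnnotation("g1", "g1", "protein", "-", (Interval(60, 180),))
        read_seq = seq[80:100] + "A" + seq[101:160]  # genomic G>A is sense C>T
        alns = [Alignment("r", 80, "+", read_seq, 1, "unique")]
        pu = build_pileup(alns, g, [gene])["g1"]
        cds_pos = 180 - 101 + 1 - 1 + 1  # position of genomic 100 on sense
        assert pu.cds_seq[cds_pos - 1] == "C"
        assert pu.base_count(cds_pos, "T") == 1

    def test_two_exon_cds_concatenates_across_the_intron(self):
        rng = np.random.default_rng(6)
        seq = _random_seq(rng, 400)
        g = _uniform_genome(seq)
        gene = GeneAnnotation("g1", "g1", "protein", "+",
                              (Interval(50, 110), Interval(200, 260)))
        read = Alignment("r", 40, "+", seq[40:240], 0, "unique")
        pu = build_pileup([read], g, [gene])["g1"]
        assert pu.cds_seq == seq[50:110] + seq[200:260]
        assert pu.depth(60) == 1  # exon 1 end
        assert pu.depth(61) == 1  # first base of exon 2 (genomic 200)
        assert pu.base_count(61, seq[200]) == 1

    def test_multi_placed_reads_are_excluded(self):
        rng = np.random.default_rng(7)
        seq = _random_seq(rng, 200)
        g = _uniform_genome(seq)
        gene = GeneAnnotation("g1", "g1", "protein", "+", (Interval(0, 90),))
        alns = [Alignment("r", 10, "+", seq[10:60], 0, "multi")]
        pu = build_pileup(alns, g, [gene])["g1"]
        assert pu.counts.sum() == 0


def _pileup_with(ref_base, depth, edited, etype="C2U"):
    """A one-gene pileup: one site of interest at CDS position 5 plus a
    padded CDS so the length is a codon multiple."""
    cds = "ATG" + "A" + ref_base + "TTTA"  # length 9
    counts = np.zeros((9, 4), dtype=np.int64)
    for i, b in enumerate(cds):
        counts[i, "ACGT".index(b)] = depth
    edited_base = "T" if etype == "C2U" else "C"
    counts[4, "ACGT".index(ref_base)] = depth - edited
    counts[4, "ACGT".index(edited_base)] = edited
    return {"g1": GenePileup("g1", cds, counts)}


class TestCallEditingSites:
    def test_depth_filter_boundary(self):
        assert call_editing_sites(_pileup_with("C", 49, 45)) == []
        called = call_editing_sites(_pileup_with("C", 50, 45))
        assert len(called) == 1 and called[0].cds_pos == 5

    def test_rate_arithmetic_and_type(self):
        (site,) = call_editing_sites(_pileup_with("C", 100, 17),
                                     min_rate=0.05)
        assert site.etype == "C2U" and site.depth == 100
        assert site.edited == 17 and site.rate == 0.17
        (u2c,) = call_editing_sites(_pileup_with("T", 100, 30, "U2C"))
        assert u2c.etype == "U2C" and u2c.rate == 0.30

    def test_min_rate_and_support_filters(self):
        assert call_editing_sites(_pileup_with("C", 100, 4),
                                  min_rate=0.05) == []
        assert call_editing_sites(_pileup_with("C", 100, 2),
                                  min_rate=0.01) == []  # < min_edited_reads
        assert len(call_editing_sites(_pileup_with("C", 100, 5),
                                      min_rate=0.05)) == 1

    def test_non_cu_mismatches_are_not_editing(self):
        pu = _pileup_with("A", 100, 0)
        pu["g1"].counts[4, 2] = 30  # A>G on the sense strand
        assert call_editing_sites(pu) == []

    def test_alignment_order_does_not_matter(self, small_plastome):
        _, genome, _, _ = small_plastome
        rng = np.random.default_rng(8)
        gene = GeneAnnotation("g1", "g1", "protein", "+", (Interval(40, 400),))
        alns = []
        for i in range(120):
            pos = int(rng.integers(0, 350))
            alns.append(Alignment(f"r{i}", pos, "+",
                                  genome.fetch(pos, pos + 100), 0, "unique"))
        a = call_editing_sites(build_pileup(alns, genome, [gene]), min_rate=0)
        random.Random(0).shuffle(alns)
        b = call_editing_sites(build_pileup(alns, genome, [gene]), min_rate=0)
        assert a == b


class TestCodonEffect:
    def test_known_effects(self):
        # TCA edited at codon position 2 -> TTA: Ser to Leu
        assert annotate_codon_effect("TCA", 2, "C2U") == \
            (2, "TCA", "TTA", "S", "L", False)
        # GCC edited at codon position 3 -> GCT: synonymous Ala
        assert annotate_codon_effect("GCC", 3, "C2U") == \
            (3, "GCC", "GCT", "A", "A", True)

    def test_exhaustive_against_frozen_translation_table(self):
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    codon = b1 + b2 + b3
                    for cpos in (1, 2, 3):
                        ref = codon[cpos - 1]
                        for etype, need, new in (("C2U", "C", "T"),
                                                 ("U2C", "T", "C")):
                            if ref != need:
                                continue
                            got = annotate_codon_effect(codon, cpos, etype)
                            edited = (codon[:cpos - 1] + new + codon[cpos:])
                            assert got == (cpos, codon, edited,
                                           CODON_TABLE_11[codon],
                                           CODON_TABLE_11[edited],
                                           CODON_TABLE_11[codon]
                                           == CODON_TABLE_11[edited])

    def test_out_of_range_position_errors(self):
        with pytest.raises(ValueError):
            annotate_codon_effect("ATGTTT", 7, "C2U")
        with pytest.warns(UserWarning, match="not divisible"):
            annotate_codon_effect("ATGTT", 2, "U2C")


def _line_pileups(rate, depth=1000):
    edited = int(round(rate * depth))
    return _pileup_with("C", depth, edited)


class TestCompareEditing:
    def test_ten_point_rule_on_divergent_rates(self):
        # reference 17.2%; 6.3% is a change (10.9 pp), 25.3% is not (8.1 pp)
        lines = {"OG": 0.172, "P88": 0.063, "P91": 0.253}
        sites, pileups = {}, {}
        for ln, rate in lines.items():
            pileups[ln] = _line_pileups(rate)
            sites[ln] = call_editing_sites(pileups[ln], min_rate=0.01)
        comps, summary = compare_editing(sites, pileups, "OG")
        (c,) = comps
        assert c.changed["P88"] is True
        assert c.changed["P91"] is False
        assert summary.set_index("line").loc["P88",
                                             "changed_sites_vs_reference"] == 1

    def test_identical_rates_are_never_changed(self):
        sites, pileups = {}, {}
        for ln in ("OG", "P1"):
            pileups[ln] = _line_pileups(0.4)
            sites[ln] = call_editing_sites(pileups[ln])
        comps, _ = compare_editing(sites, pileups, "OG")
        assert comps[0].changed["P1"] is False

    def test_covered_but_uncalled_site_counts_as_rate_zero(self):
        pileups = {"OG": _line_pileups(0.5), "P1": _line_pileups(0.0)}
        sites = {ln: call_editing_sites(pu) for ln, pu in pileups.items()}
        assert sites["P1"] == []
        comps, _ = compare_editing(sites, pileups, "OG")
        assert comps[0].rates["P1"] == 0.0
        assert comps[0].changed["P1"] is True

    def test_low_coverage_line_is_not_comparable(self):
        pileups = {"OG": _line_pileups(0.5),
                   "P1": _pileup_with("C", 30, 15)}
        sites = {"OG": call_editing_sites(pileups["OG"]), "P1": []}
        comps, _ = compare_editing(sites, pileups, "OG")
        assert comps[0].rates["P1"] is None
        assert comps[0].changed["P1"] is None

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            compare_editing({"P1": []}, {"P1": {}}, "OG")

    def test_summary_inequalities_on_simulated_lines(self):
        sites = [synthio.EditingSpec("pg001", 30, "C2U", 0.6),
                 synthio.EditingSpec("pg001", 90, "C2U", 0.3),
                 synthio.EditingSpec("pg002", 45, "U2C", 0.8)]
        cfg = synthio.SimulationConfig(
            seed=31, lsc_len=4000, ssc_len=900, ir_len=1200, n_repeats=0,
            n_genes=6, gene_len_range=(300, 600), editing_sites=sites,
            rna_depth=200, rna_read_len=100, error_rate=0.001)
        genome, ann, truth = synthio.generate_plastome(cfg)
        reads = synthio.simulate_rna_reads(genome, ann, truth, cfg)
        pu = build_pileup(naive_map(reads, genome), genome, ann)
        called = call_editing_sites(pu)
        assert {s.key for s in called} == {"pg001-30", "pg001-90", "pg002-45"}
        n_genes = len({s.gene_id for s in called})
        assert n_genes <= len(called)
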