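"""Generator contracts: construction, determinism, read populations."""

import math

import pytest

from plastiq import synthio
from plastiq.genome import revcomp
from plastiq.synthio import (ConfigurationError, EditingSpec,
                             SimulationConfig, generate_plastome,
                             simulate_dna_reads, simulate_rna_reads)


def test_bare_quadripartite_construction():
    cfg = SimulationConfig(seed=0, lsc_len=5000, ssc_len=1000, ir_len=1500,
                           n_repeats=0, n_genes=0)
    genome, annotations, truth = generate_plastome(cfg)
    assert len(genome) == 9000
    assert annotations == []
    ira = genome.fetch_interval(truth.regions["ira"])
    irb = genome.fetch_interval(truth.regions["irb"])
    assert irb == revcomp(ira)


def test_planted_repeat_copies_are_exact(small_plastome):
    _, genome, _, truth = small_plastome
    assert len(truth.repeats) == 2
    for r in truth.repeats:
        u1 = genome.fetch_interval(r.copy1)
        u2 = genome.fetch_interval(r.copy2)
        assert u1 == (u2 if r.orientation == "direct" else revcomp(u2))
        assert r.unit_len == len(u1) > 20


def test_fixed_seed_is_bit_identical(small_plastome):
    cfg, genome, _, truth = small_plastome
    genome2, _, truth2 = generate_plastome(cfg)
    assert genome2.seq == genome.seq
    assert truth2.to_frame().equals(truth.to_frame())
    r1 = simulate_dna_reads(genome, truth, cfg)
    r2 = simulate_dna_reads(genome2, truth2, cfg)
    assert [(a.name, a.seq) for a in r1] == [(b.name, b.seq) for b in r2]


def test_infeasible_packing_is_a_configuration_error():
    cfg = SimulationConfig(seed=0, lsc_len=1000, ssc_len=400, ir_len=500,
                           n_genes=6, gene_len_range=(300, 300), n_repeats=0)
    with pytest.raises(ConfigurationError):
        generate_plastome(cfg)


def test_editing_site_validation():
    base = dict(seed=0, lsc_len=4000, ssc_len=900, ir_len=1200, n_repeats=0,
                n_genes=6, gene_len_range=(300, 600))
    with pytest.raises(ConfigurationError, match="outside any CDS"):
        generate_plastome(SimulationConfig(
            **base, editing_sites=[EditingSpec("trn01", 5, "C2U", 0.5)]))
    with pytest.raises(ConfigurationError, match="beyond CDS"):
        generate_plastome(SimulationConfig(
            **base, editing_sites=[EditingSpec("pg001", 10_000, "C2U", 0.5)]))
    with pytest.raises(ConfigurationError):
        SimulationConfig(**base,
                         editing_sites=[EditingSpec("pg001", 5, "C2U", 1.5)]
                         ).validate()


def test_read_length_exceeding_genome_is_rejected(small_plastome):
    cfg, genome, _, truth = small_plastome
    bad = synthio.SimulationConfig(**{**vars(cfg),
                                      "dna_read_len_range": (500, 10_000)})
    with pytest.raises(ConfigurationError):
        simulate_dna_reads(genome, truth, bad)


def test_error_free_read_matches_genome_substring(small_plastome):
    cfg, genome, _, truth = small_plastome
    clean = synthio.SimulationConfig(**{**vars(cfg), "error_rate": 0.0})
    reads = simulate_dna_reads(genome, truth, clean)
    checked = 0
    for r in reads[:50]:
        if r.tag("pool") != "parental":
            continue
        start, n = int(r.tag("start")), int(r.tag("len"))
        expect = genome.fetch(start, start + n)
        if r.tag("strand") == "-":
            expect = revcomp(expect)
        assert r.seq == expect
        checked += 1
    assert checked > 10


def test_zero_recombination_yields_only_parental_junctions(small_plastome):
    cfg, genome, _, truth = small_plastome
    clean = synthio.SimulationConfig(**{**vars(cfg), "error_rate": 0.0,
                                        "dna_depth": 20.0})
    reads = simulate_dna_reads(genome, truth, clean)
    n_junction = 0
    for r in reads:
        jx = r.tag("jx")
        assert r.tag("pool") == "parental"
        if jx != "-":
            for part in jx.split("+"):
                assert part.split(":")[1] in ("ab", "cd")
                n_junction += 1
    assert n_junction > 20


def test_recombinant_fraction_recovers_binomially():
    cfg = SimulationConfig(seed=9, lsc_len=3000, ssc_len=800, ir_len=1000,
                           n_repeats=1, n_genes=2, gene_len_range=(150, 300),
                           repeat_lengths=[40], repeat_orientations=["direct"],
                           recomb_fraction=0.5, flank_len=100,
                           dna_read_len_range=(600, 800), dna_depth=300,
                           error_rate=0.0, rna_depth=1)
    genome, _, truth = generate_plastome(cfg)
    reads = simulate_dna_reads(genome, truth, cfg)
    n_par = n_rec = 0
    for r in reads:
        jx = r.tag("jx")
        if jx == "-":
            continue
        for part in jx.split("+"):
            lab = part.split(":")[1]
            if lab in ("ab", "cd"):
                n_par += 1
            else:
                n_rec += 1
    n = n_par + n_rec
    assert n > 500
    se = math.sqrt(0.5 * 0.5 / n)
    assert abs(n_rec / n - 0.5) <= 3 * se


def test_base_error_fraction_converges():
    cfg = SimulationConfig(seed=5, lsc_len=3000, ssc_len=800, ir_len=1000,
                           n_repeats=0, n_genes=2, gene_len_range=(150, 300),
                           dna_read_len_range=(500, 700), dna_depth=50,
                           error_rate=0.02, rna_depth=1)
    genome, _, truth = generate_plastome(cfg)
    reads = simulate_dna_reads(genome, truth, cfg)
    n_err = n_tot = 0
    for r in reads:
        start, n = int(r.tag("start")), int(r.tag("len"))
        expect = genome.fetch(start, start + n)
        if r.tag("strand") == "-":
            expect = revcomp(expect)
        n_err += sum(a != b for a, b in zip(r.seq, expect))
        n_tot += n
    se = math.sqrt(0.02 * 0.98 / n_tot)
    assert abs(n_err / n_tot - 0.02) <= 3 * se


def _rna_setup(**over):
    kw = dict(seed=21, lsc_len=4000, ssc_len=900, ir_len=1200,
              n_repeats=0, n_genes=6, gene_len_range=(300, 600),
              rna_read_len=100, error_rate=0.0)
    kw.update(over)
    cfg = SimulationConfig(**kw)
    genome, ann, truth = generate_plastome(cfg)
    return cfg, genome, ann, truth


def test_full_editing_rate_edits_every_covering_read():
    cfg, genome, ann, truth = _rna_setup(
        editing_sites=[EditingSpec("pg001", 58, "C2U", 1.0)], rna_depth=50)
    reads = simulate_rna_reads(genome, ann, truth, cfg)
    gene = next(a for a in ann if a.name == "pg001")
    t = gene.spliced_seq(genome)
    assert t[57] == "C"
    n_cover = 0
    for r in reads:
        if r.tag("gene") != "pg001":
            continue
        start, n = int(r.tag("start")), int(r.tag("len"))
        off = 57 - start
        if 0 <= off < n:
            seq = r.seq if r.tag("strand") == "+" else revcomp(r.seq)
            assert seq[off] == "T"
            n_cover += 1
    assert n_cover >= 30


def test_partial_editing_rate_recovers_binomially():
    cfg, genome, ann, truth = _rna_setup(
        editing_sites=[EditingSpec("pg001", 58, "C2U", 0.172)], rna_depth=900)
    reads = simulate_rna_reads(genome, ann, truth, cfg)
    edited = covered = 0
    for r in reads:
        if r.tag("gene") != "pg001":
            continue
        start, n = int(r.tag("start")), int(r.tag("len"))
        if 0 <= 57 - start < n:
            covered += 1
            edited += "58" in (r.tag("ed") or "-").split(",")
    assert covered >= 500
    se = math.sqrt(0.172 * 0.828 / covered)
    assert abs(edited / covered - 0.172) <= 3 * se


def test_expression_levels_drive_read_count_ratio():
    cfg, genome, ann, truth = _rna_setup(
        gene_len_range=(400, 400), rna_depth=150,
        expression_levels={"pg001": 1.0, "pg002": 4.0})
    reads = simulate_rna_reads(genome, ann, truth, cfg)
    counts = {"pg001": 0, "pg002": 0}
    for r in reads:
        gid = r.tag("gene")
        if gid in counts:
            counts[gid] += 1
    n = counts["pg001"] + counts["pg002"]
    p = counts["pg002"] / n
    se = math.sqrt(0.8 * 0.2 / n)
    assert abs(p - 0.8) <= 3 * se
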