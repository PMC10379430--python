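"""Dispersed-repeat discovery, configurations and gene proximity."""

import numpy as np
import pytest
from _oracles import brute_force_repeat_pairs, match_keys

from plastiq import structure, synthio
from plastiq.genome import CircularGenome, Interval, revcomp
from plastiq.repeatscan import (RepeatType, enumerate_configurations,
                                excise_ir, find_repeat_matches, find_repeats,
                                repeat_coverage, repeats_near_genes)
from plastiq.structure import GeneAnnotation


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_repeat_free_random_sequence_yields_nothing():
    rng = np.random.default_rng(17)
    seq = _random_seq(rng, 1000)
    # certify the fixture with the exhaustive oracle first
    assert brute_force_repeat_pairs(seq, min_len=21) == set()
    g = CircularGenome("r", seq)
    assert find_repeat_matches(g) == []
    scan = find_repeats(g)
    assert scan.types == [] and scan.families == []
    assert repeat_coverage(scan, g) == 0.0


def test_planted_repeats_found_at_exact_loci(small_plastome):
    _, genome, _, truth = small_plastome
    st = structure.detect_quadripartite(genome)
    reduced, offset = excise_ir(genome, st)
    assert offset == 0
    scan = find_repeats(reduced)
    got = {(t.orientation, t.copy1.start, t.copy1.end,
            t.copy2.start, t.copy2.end) for t in scan.types}
    want = {(r.orientation, r.copy1.start, r.copy1.end,
             r.copy2.start, r.copy2.end) for r in truth.repeats}
    assert got == want
    for t in scan.types:
        assert t.identity == 1.0
        u1 = reduced.fetch_interval(t.copy1)
        u2 = reduced.fetch_interval(t.copy2)
        assert u1 == (u2 if t.orientation == "direct" else revcomp(u2))
        assert t.repeat_id[0] == ("D" if t.orientation == "direct" else "I")


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_matches_equal_brute_force_scan(seed):
    cfg = synthio.SimulationConfig(
        seed=seed, lsc_len=1200, ssc_len=400, ir_len=500, n_repeats=2,
        n_genes=2, gene_len_range=(100, 200), repeat_lengths=[30, 45],
        flank_len=60, dna_depth=1, rna_depth=1, dna_read_len_range=(100, 200))
    genome, _, _ = synthio.generate_plastome(cfg)
    reduced, _ = excise_ir(genome,
                           structure.detect_quadripartite(genome, 400))
    impl = match_keys(find_repeat_matches(reduced), len(reduced))
    assert impl == brute_force_repeat_pairs(reduced.seq)


def test_scan_is_rotation_invariant(small_plastome):
    _, genome, _, _ = small_plastome
    reduced, _ = excise_ir(genome, structure.detect_quadripartite(genome))
    base = {(t.orientation, t.length) for t in find_repeats(reduced).types}
    rot = find_repeats(reduced.rotate(911))
    assert {(t.orientation, t.length) for t in rot.types} == base


def test_repeat_coverage_arithmetic():
    rng = np.random.default_rng(5)
    g = CircularGenome("t", _random_seq(rng, 10_000))
    t = RepeatType("D1", "direct", 50, 1.0,
                   Interval(100, 150), Interval(5000, 5050))
    assert repeat_coverage([t], g) == 1.0


def _planted_config_genome(orientation):
    rng = np.random.default_rng(11)
    a, b, c, d = (_random_seq(rng, 200) for _ in range(4))
    unit = _random_seq(rng, 40)
    filler1, filler2 = _random_seq(rng, 800), _random_seq(rng, 800)
    copy2 = unit if orientation == "direct" else revcomp(unit)
    seq = a + unit + b + filler1 + c + copy2 + d + filler2
    g = CircularGenome("cfg", seq)
    s1 = 200
    s2 = 200 + 40 + 200 + 800 + 200
    rep = RepeatType("R1", orientation, 40, 1.0,
                     Interval(s1, s1 + 40), Interval(s2, s2 + 40))
    return g, rep, (a, b, c, d, unit)


def test_direct_configuration_junctions_are_flank_products():
    g, rep, (a, b, c, d, unit) = _planted_config_genome("direct")
    cfgs = enumerate_configurations(rep, g, flank_len=200)
    assert cfgs["ab"].junction == a + unit + b
    assert cfgs["cd"].junction == c + unit + d
    assert cfgs["ad"].junction == a + unit + d
    assert cfgs["cb"].junction == c + unit + b
    assert len({x.junction for x in cfgs.values()}) == 4
    assert cfgs["ab"].configuration_class == "parental"
    assert cfgs["ad"].configuration_class == "recombinant"
    # parental junctions occur in the genome, recombinant ones do not
    doubled = g.seq + g.seq
    for lab in ("ab", "cd"):
        j = cfgs[lab].junction
        assert j in doubled or revcomp(j) in doubled
    for lab in ("ad", "cb"):
        j = cfgs[lab].junction
        assert j not in doubled and revcomp(j) not in doubled


def test_inverted_configuration_junctions_use_reverse_complement_flanks():
    g, rep, (a, b, c, d, unit) = _planted_config_genome("inverted")
    cfgs = enumerate_configurations(rep, g, flank_len=200)
    # copy-2 flanks in the unit frame: c = rc(downstream), d = rc(upstream)
    assert cfgs["cd"].junction == revcomp(d) + unit + revcomp(c)
    assert cfgs["ad"].junction == a + unit + revcomp(c)
    doubled = g.seq + g.seq
    for lab in ("ab", "cd"):
        j = cfgs[lab].junction
        assert j in doubled or revcomp(j) in doubled
    for lab in ("ad", "cb"):
        j = cfgs[lab].junction
        assert j not in doubled and revcomp(j) not in doubled


def test_flank_shrinks_near_other_copy_and_errors_below_anchor():
    rng = np.random.default_rng(13)
    unit = _random_seq(rng, 30)
    # copies only 120 bp apart: flanks must shrink below the requested 200
    seq = (_random_seq(rng, 500) + unit + _random_seq(rng, 120) + unit
           + _random_seq(rng, 500))
    g = CircularGenome("t", seq)
    rep = RepeatType("R1", "direct", 30, 1.0, Interval(500, 530),
                     Interval(650, 680))
    with pytest.warns(UserWarning, match="flank shrunk"):
        cfgs = enumerate_configurations(rep, g, flank_len=200, min_flank=50)
    assert len(cfgs["ab"].junction) == 30 + 2 * 120
    with pytest.raises(ValueError, match="usable flank"):
        enumerate_configurations(rep, g, flank_len=200, min_flank=150)


def _gene_at(start, end):
    return GeneAnnotation("g", "g", "protein", "+", (Interval(start, end),))


def test_gene_proximity_window_boundaries():
    L = 20_000
    rep = RepeatType("R1", "direct", 50, 1.0, Interval(10_000, 10_050),
                     Interval(15_000, 15_050))
    near = _gene_at(10_050 + 1999, 10_050 + 1999 + 300)
    far = _gene_at(10_050 + 2001, 10_050 + 2001 + 300)
    rf, gf = repeats_near_genes([rep], [near], L, window=2000)
    assert rf["R1"] and gf["g"]
    rf, gf = repeats_near_genes([rep], [far], L, window=2000)
    assert not rf["R1"] and not gf["g"]


def test_gene_proximity_across_origin_matches_rotation():
    L = 20_000
    rep = RepeatType("R1", "direct", 50, 1.0, Interval(19_900, 19_950),
                     Interval(5_000, 5_050))
    gene = _gene_at(100, 400)  # 150 bp past the origin from copy1
    rf, _ = repeats_near_genes([rep], [gene], L, window=2000)
    # same configuration rotated away from the origin
    shift = 3000
    s = (19_900 + shift) % L
    rep2 = RepeatType("R1", "direct", 50, 1.0, Interval(s, s + 50),
                      Interval(5_000 + shift, 5_050 + shift))
    gene2 = _gene_at(100 + shift, 400 + shift)
    rf2, _ = repeats_near_genes([rep2], [gene2], L, window=2000)
    assert rf["R1"] == rf2["R1"] is True
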