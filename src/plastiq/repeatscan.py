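"""Dispersed-repeat discovery and repeat-configuration enumeration.

A dispersed two-copy repeat splits the genome into four flanking sequences:
``a``/``b`` upstream/downstream of copy 1 and ``c``/``d`` of copy 2. The
parental molecule carries junctions ``a-R-b`` and ``c-R-d``; homologous
recombination between the copies exchanges the downstream flanks and yields
the recombinant junctions ``a-R-d`` and ``c-R-b``. Scanning is done on a
genome with one IR copy excised so the large inverted repeat itself does not
swamp the dispersed-repeat census.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._match import MatchPair, direct_maximal_matches, inverted_maximal_matches
from .genome import (CircularGenome, Interval, circular_gap,
                     interval_union_size, intervals_overlap, normalize,
                     revcomp)
from .structure import GeneAnnotation, QuadripartiteStructure


@dataclass(frozen=True)
class RepeatConfiguration:
    """One of the four flank arrangements of a two-copy repeat."""

    repeat_id: str
    label: str  # 'ab' | 'cd' | 'ad' | 'cb'
    junction: str  # flank_left + repeat unit + flank_right
    unit_len: int
    flank_len: int

    PARENTAL = ("ab", "cd")
    RECOMBINANT = ("ad", "cb")

    def __post_init__(self) -> None:
        if len(self.junction) != self.unit_len + 2 * self.flank_len:
            raise ValueError("junction length inconsistent with unit/flank lengths")

    @property
    def configuration_class(self) -> str:
        return "parental" if self.label in self.PARENTAL else "recombinant"


@dataclass
class RepeatType:
    """A dispersed repeat with exactly two copies, amenable to configuration
    analysis. Copy intervals are on the scanned (IR-reduced) genome; ``copy1``
    is the copy with the smaller start coordinate."""

    repeat_id: str
    orientation: str  # 'direct' | 'inverted'
    length: int
    identity: float
    copy1: Interval
    copy2: Interval
    unit: str = field(repr=False, default="")


@dataclass
class RepeatFamily:
    """A repeat with three or more copies (reported, but excluded from the
    two-product configuration analysis)."""

    family_id: str
    copies: list[Interval]
    length: int


@dataclass
class RepeatScanResult:
    types: list[RepeatType]
    families: list[RepeatFamily]
    matches: list[MatchPair]
    tandem: list[MatchPair]
    genome_length: int


def excise_ir(genome: CircularGenome,
              structure: QuadripartiteStructure) -> tuple[CircularGenome, int]:
    """Genome with the IRb copy removed (LSC + IRa + SSC), rotated so the LSC
    starts at 0. Dispersed-repeat scans run on this reduced circle.

    Returns ``(reduced_genome, offset)`` where a reduced coordinate ``p``
    corresponds to ``(offset + p) % L`` on the full circle (the LSC, IRa and
    SSC arcs are contiguous by the structure convention).
    """
    seq = (genome.fetch_interval(structure.lsc)
           + genome.fetch_interval(structure.ira)
           + genome.fetch_interval(structure.ssc))
    offset = normalize(structure.lsc, len(genome)).start
    return CircularGenome(genome.id + "|IR-reduced", seq), offset


def find_repeat_matches(genome: CircularGenome, word_size: int = 20,
                        min_len: int = 21, min_identity: float = 1.0,
                        ) -> list[MatchPair]:
    """All maximal ungapped repeated pairs (> 20 bp by default) of the
    circular genome, in both orientations, seeded by exact ``word_size``-mers.
    With ``min_identity=1.0`` this is exactly the set of maximal exact
    duplications."""
    frac = 1.0 - min_identity
    matches = (direct_maximal_matches(genome.seq, word_size, min_len, frac)
               + inverted_maximal_matches(genome.seq, word_size, min_len, frac))
    return [m for m in matches if m.identity >= min_identity]


def _merge_copies(matches: list[MatchPair], L: int) -> list[list]:
    """Union-find over copy intervals: overlapping intervals are the same
    copy; connected components are repeat families."""
    nodes: list[Interval] = []

    def node_of(iv: Interval) -> int:
        for k, other in enumerate(nodes):
            if intervals_overlap(iv, other, L):
                # widen the stored interval to the union extent
                s = min(normalize(iv, L).start, normalize(other, L).start)
                e = max(normalize(iv, L).end, normalize(other, L).end)
                nodes[k] = Interval(s, e)
                return k
        nodes.append(normalize(iv, L))
        return len(nodes) - 1

    parent: list[int] = []

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for m in matches:
        u, v = node_of(m.copy1), node_of(m.copy2)
        while len(parent) < len(nodes):
            parent.append(len(parent))
        parent[find(u)] = find(v)
        edges.append((u, v, m))
    comps: dict[int, dict] = {}
    for u, v, m in edges:
        r = find(u)
        comp = comps.setdefault(r, {"nodes": set(), "matches": []})
        comp["nodes"].update((u, v))
        comp["matches"].append(m)
    return [{"copies": sorted(nodes[k] for k in comp["nodes"]),
             "matches": comp["matches"]} for comp in comps.values()]


def find_repeats(genome: CircularGenome, word_size: int = 20,
                 min_len: int = 21, min_identity: float = 1.0,
                 ) -> RepeatScanResult:
    """Group maximal repeated pairs into repeat types.

    Tandem pairs (overlapping or abutting copies) and palindromic spans are
    set aside; families with more than two copies are reported separately.
    Two-copy types get sequential ids prefixed D (direct) or I (inverted) in
    genome order.
    """
    L = len(genome)
    matches = find_repeat_matches(genome, word_size, min_len, min_identity)
    tandem = [m for m in matches
              if circular_gap(m.copy1, m.copy2, L) == 0]
    dispersed = [m for m in matches if m not in tandem]
    types: list[RepeatType] = []
    families: list[RepeatFamily] = []
    for comp in _merge_copies(dispersed, L):
        copies = comp["copies"]
        if len(copies) == 2 and len(comp["matches"]) == 1:
            m = comp["matches"][0]
            types.append(RepeatType(
                repeat_id="", orientation=m.orientation, length=m.length,
                identity=m.identity, copy1=m.copy1, copy2=m.copy2,
                unit=genome.fetch_interval(m.copy1)))
        else:
            families.append(RepeatFamily(
                family_id="", copies=list(copies),
                length=max(m.length for m in comp["matches"])))
    types.sort(key=lambda t: (t.copy1.start, t.copy2.start))
    nd = ni = 0
    for t in types:
        if t.orientation == "direct":
            nd += 1
            t.repeat_id = f"D{nd}"
        else:
            ni += 1
            t.repeat_id = f"I{ni}"
    families.sort(key=lambda f: f.copies[0].start)
    for k, f in enumerate(families, 1):
        f.family_id = f"F{k}"
    return RepeatScanResult(types=types, families=families, matches=matches,
                            tandem=tandem, genome_length=L)


def repeat_coverage(result: RepeatScanResult | list[RepeatType],
                    genome: CircularGenome) -> float:
    """Percentage of the genome covered by the base-wise union of repeat
    copies, to 2 decimals."""
    if isinstance(result, RepeatScanResult):
        intervals = [iv for t in result.types for iv in (t.copy1, t.copy2)]
        intervals += [iv for f in result.families for iv in f.copies]
    else:
        intervals = [iv for t in result for iv in (t.copy1, t.copy2)]
    if not intervals:
        return 0.0
    return round(100.0 * interval_union_size(intervals, len(genome)) / len(genome), 2)


def enumerate_configurations(repeat: RepeatType, genome: CircularGenome,
                             flank_len: int = 200, min_flank: int = 50,
                             other_copies: list[Interval] | None = None,
                             ) -> dict[str, RepeatConfiguration]:
    """The four junction sequences (ab, cd, ad, cb) of a two-copy repeat.

    Flanks are taken in the orientation of copy 1's repeat unit, so for an
    inverted repeat the copy-2 flanks are reverse-complemented genomic
    context. If a flank would run into another repeat copy it is shrunk with
    a warning; below ``min_flank`` anchored classification is impossible and
    an error is raised.
    """
    L = len(genome)
    c1 = normalize(repeat.copy1, L)
    c2 = normalize(repeat.copy2, L)
    gap_between = circular_gap(c1, c2, L)
    limits = [gap_between]
    for blocker in other_copies or []:
        if blocker in (c1, c2):
            continue
        limits.append(circular_gap(c1, blocker, L))
        limits.append(circular_gap(c2, blocker, L))
    limit = min(limits)
    eff = flank_len
    if limit < eff:
        eff = limit
        warnings.warn(
            f"{repeat.repeat_id}: flank shrunk to {eff} bp to avoid the other "
            f"repeat copy", stacklevel=2)
    if eff < min_flank:
        raise ValueError(
            f"{repeat.repeat_id}: usable flank {eff} bp < minimum anchor "
            f"{min_flank} bp")
    unit = genome.fetch_interval(c1)
    a = genome.fetch(c1.start - eff, c1.start)
    b = genome.fetch(c1.end, c1.end + eff)
    if repeat.orientation == "direct":
        c = genome.fetch(c2.start - eff, c2.start)
        d = genome.fetch(c2.end, c2.end + eff)
    else:
        c = revcomp(genome.fetch(c2.end, c2.end + eff))
        d = revcomp(genome.fetch(c2.start - eff, c2.start))
    junctions = {"ab": a + unit + b, "cd": c + unit + d,
                 "ad": a + unit + d, "cb": c + unit + b}
    if len(set(junctions.values())) != 4:
        raise ValueError(f"{repeat.repeat_id}: junction sequences not distinct")
    return {lab: RepeatConfiguration(repeat.repeat_id, lab, seq,
                                     unit_len=len(unit), flank_len=eff)
            for lab, seq in junctions.items()}


def repeats_near_genes(result: RepeatScanResult | list[RepeatType],
                       annotations: list[GeneAnnotation], genome_length: int,
                       window: int = 2000) -> tuple[dict[str, bool], dict[str, bool]]:
    """Which repeats lie within ``window`` bp of a gene, and vice versa.

    Distance is circular gap between the repeat copy interval and the gene
    extent; a repeat copy overlapping a gene counts as distance 0.
    Returns (per-repeat flags, per-gene flags).
    """
    types = result.types if isinstance(result, RepeatScanResult) else result
    repeat_flag = {t.repeat_id: False for t in types}
    gene_flag = {g.gene_id: False for g in annotations}
    for t in types:
        for g in annotations:
            dist = min(circular_gap(t.copy1, g.extent(), genome_length),
                       circular_gap(t.copy2, g.extent(), genome_length))
            if dist <= window:
                repeat_flag[t.repeat_id] = True
                gene_flag[g.gene_id] = True
    return repeat_flag, gene_flag
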