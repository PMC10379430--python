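"""Quadripartite plastome structure and genome-level summary statistics.

Angiosperm plastomes carry two large inverted-repeat copies (IRa/IRb)
separating a large and a small single-copy region (LSC/SSC). This module
detects that structure from the sequence alone, computes the usual summary
statistics (genome size, GC content, gene vs non-gene region sizes) and
performs a simple circular gene-order/orientation comparison between lines.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._match import inverted_maximal_matches
from .genome import (CircularGenome, Interval, interval_union_size,
                     intervals_overlap, normalize, revcomp)


class StructureAbsentError(ValueError):
    """No inverted-repeat pair of the required size exists."""


class AmbiguousStructureError(ValueError):
    """More than one maximal inverted-repeat candidate of equal length."""


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC / IRa / SSC / IRb partition of a circular plastome.

    By convention IRa is the IR copy immediately following the LSC in
    ascending coordinates, so the circle reads LSC, IRa, SSC, IRb.
    """

    lsc: Interval
    ira: Interval
    ssc: Interval
    irb: Interval
    genome_length: int
    ir_mismatches: int = 0

    @property
    def lsc_size(self) -> int:
        return len(self.lsc)

    @property
    def ssc_size(self) -> int:
        return len(self.ssc)

    @property
    def ir_size(self) -> int:
        return len(self.ira)

    def region_of(self, pos: int) -> str:
        p = pos % self.genome_length
        for name in ("lsc", "ira", "ssc", "irb"):
            iv = normalize(getattr(self, name), self.genome_length)
            if iv.start <= p < iv.end or (iv.end > self.genome_length
                                          and p < iv.end - self.genome_length):
                return name
        raise AssertionError("quadripartite intervals do not cover the circle")


@dataclass
class GeneAnnotation:
    """A gene model on a circular genome.

    ``exons`` are stored in ascending genome order regardless of strand; the
    spliced sense-strand sequence of a minus-strand gene is the reverse
    complement of the concatenated exon sequence.
    """

    gene_id: str
    name: str
    ftype: str  # 'protein' | 'tRNA' | 'rRNA'
    strand: str  # '+' | '-'
    exons: tuple[Interval, ...]
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in ("protein", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        self.exons = tuple(ex)

    def extent(self) -> Interval:
        """First exon start to last exon end (introns included)."""
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def spliced_seq(self, genome: CircularGenome) -> str:
        s = "".join(genome.fetch_interval(e) for e in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def sense_positions(self, L: int) -> list[int]:
        """Genome coordinates of spliced positions, in sense (5'->3') order."""
        pos = [p % L for e in self.exons for p in range(e.start, e.end)]
        return pos[::-1] if self.strand == "-" else pos


def detect_quadripartite(genome: CircularGenome, min_ir_len: int = 1000,
                         max_mismatch_frac: float = 0.0) -> QuadripartiteStructure:
    """Locate the maximal inverted-repeat pair and the two single-copy arcs.

    The longest pair of disjoint inverted repeats of at least ``min_ir_len``
    defines IRa/IRb; the larger remaining arc is the LSC. Raises
    :class:`StructureAbsentError` when no qualifying pair exists and
    :class:`AmbiguousStructureError` when two distinct maximal pairs tie.
    """
    if min_ir_len < 1:
        raise ValueError("min_ir_len must be >= 1")
    L = len(genome)
    word = min(32, min_ir_len)
    matches = inverted_maximal_matches(genome.seq, word, min_ir_len,
                                       max_mismatch_frac)
    cands = [m for m in matches
             if not intervals_overlap(m.copy1, m.copy2, L)]
    if not cands:
        raise StructureAbsentError(
            f"no disjoint inverted repeat >= {min_ir_len} bp in {genome.id!r}")
    best_len = max(m.length for m in cands)
    best = [m for m in cands if m.length == best_len]
    if len(best) > 1:
        raise AmbiguousStructureError(
            f"{len(best)} maximal inverted-repeat candidates of {best_len} bp")
    m = best[0]
    i1, i2 = normalize(m.copy1, L), normalize(m.copy2, L)
    gap12 = (i2.start - i1.end) % L  # arc from end of copy1 to start of copy2
    gap21 = (i1.start - i2.end) % L
    if gap12 == 0 or gap21 == 0:
        raise StructureAbsentError(
            "inverted repeats are adjacent; no two single-copy regions")
    arc12 = Interval(i1.end % L, i1.end % L + gap12)
    arc21 = Interval(i2.end % L, i2.end % L + gap21)
    if len(arc12) >= len(arc21):
        lsc, ssc = arc12, arc21
        ira, irb = i2, i1  # IR following the LSC is IRa
    else:
        lsc, ssc = arc21, arc12
        ira, irb = i1, i2
    return QuadripartiteStructure(lsc=lsc, ira=ira, ssc=ssc, irb=irb,
                                  genome_length=L, ir_mismatches=m.mismatches)


def canonical_rotation(genome: CircularGenome,
                       structure: QuadripartiteStructure | None = None,
                       ) -> tuple[CircularGenome, QuadripartiteStructure]:
    """Rotate so the LSC starts at position 0 (reporting convention)."""
    if structure is None:
        structure = detect_quadripartite(genome)
    L = len(genome)
    off = normalize(structure.lsc, L).start
    rot = genome.rotate(off)

    def shift(iv: Interval) -> Interval:
        s = (normalize(iv, L).start - off) % L
        return Interval(s, s + len(iv))

    moved = QuadripartiteStructure(
        lsc=shift(structure.lsc), ira=shift(structure.ira),
        ssc=shift(structure.ssc), irb=shift(structure.irb),
        genome_length=L, ir_mismatches=structure.ir_mismatches)
    return rot, moved


def gc_content(genome: CircularGenome) -> float:
    """GC percentage over unambiguous bases, to 2 decimals (N excluded)."""
    counts = {b: genome.seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return round(100.0 * (counts["G"] + counts["C"]) / denom, 2)


def region_sizes(genome: CircularGenome,
                 annotations: list[GeneAnnotation]) -> tuple[int, int]:
    """(gene region, non-gene region) sizes in bp.

    The gene region is the base-wise union of gene extents (introns included,
    both strands, IR-duplicated genes at both loci); overlaps count once, so
    the two sizes always sum to the genome length.
    """
    L = len(genome)
    gene = interval_union_size([g.extent() for g in annotations], L)
    return gene, L - gene


@dataclass(frozen=True)
class OrderDiff:
    gene_id: str
    kind: str  # 'order' | 'orientation' | 'missing_in_a' | 'missing_in_b'


def compare_gene_order(a: list[GeneAnnotation],
                       b: list[GeneAnnotation]) -> list[OrderDiff]:
    """Genes whose circular rank order or strand differ between two lines.

    A light-weight stand-in for whole-genome alignment: sufficient to flag
    inversions/translocations at gene resolution. Genes present in only one
    annotation set are reported as presence/absence differences.
    """
    by_id_a = {g.gene_id: g for g in a}
    by_id_b = {g.gene_id: g for g in b}
    diffs: list[OrderDiff] = []
    for gid in sorted(by_id_a.keys() - by_id_b.keys()):
        diffs.append(OrderDiff(gid, "missing_in_b"))
    for gid in sorted(by_id_b.keys() - by_id_a.keys()):
        diffs.append(OrderDiff(gid, "missing_in_a"))
    shared = by_id_a.keys() & by_id_b.keys()
    if not shared:
        return diffs
    order_a = [g.gene_id for g in sorted(a, key=lambda g: g.extent().start)
               if g.gene_id in shared]
    order_b = [g.gene_id for g in sorted(b, key=lambda g: g.extent().start)
               if g.gene_id in shared]
    # circular alignment: rotate b's order to start at a's first gene
    pivot = order_b.index(order_a[0])
    order_b = order_b[pivot:] + order_b[:pivot]
    changed = {ga for ga, gb in zip(order_a, order_b) if ga != gb}
    for gid in sorted(changed):
        diffs.append(OrderDiff(gid, "order"))
    for gid in sorted(shared):
        if by_id_a[gid].strand != by_id_b[gid].strand:
            diffs.append(OrderDiff(gid, "orientation"))
    return diffs


def structure_table_row(line_id: str, genome: CircularGenome,
                        annotations: list[GeneAnnotation],
                        structure: QuadripartiteStructure | None = None) -> dict:
    """One line of the per-line structure summary (genome size, GC, region
    sizes), the shape conventionally tabulated for plastome comparisons."""
    if structure is None:
        structure = detect_quadripartite(genome)
    gene, non_gene = region_sizes(genome, annotations)
    return {
        "line": line_id,
        "genome_size_bp": len(genome),
        "gc_content_pct": gc_content(genome),
        "gene_region_bp": gene,
        "non_gene_region_bp": non_gene,
        "lsc_size_bp": structure.lsc_size,
        "ssc_size_bp": structure.ssc_size,
        "ir_size_bp": structure.ir_size,
    }
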