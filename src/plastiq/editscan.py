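"""RNA-editing detection in protein-coding regions.

Organellar transcripts undergo C-to-U (and more rarely U-to-C) editing.
Sites are called from strand-resolved pileups over annotated CDS: a
sense-strand reference C showing T in reads is a C2U candidate, a reference
T showing C a U2C candidate; the editing rate is edited reads over coverage.
Sites are compared across lines against a reference (maternal) line, a site
counting as editing-rate-changed when its rate differs by more than a
threshold in absolute percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .genome import CircularGenome, revcomp, complement
from .io import SeqRead
from .structure import GeneAnnotation

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


@dataclass
class Alignment:
    """An ungapped placement of a read on the circular genome; ``seq`` is
    stored in forward-genome orientation."""

    read_id: str
    pos: int  # 0-based leftmost coordinate (may wrap)
    strand: str  # '+' | '-'
    seq: str
    nm: int  # mismatch count
    status: str  # 'unique' | 'multi' | 'unaligned'
    # every equally-best placement; lets expression counting keep multi-reads
    # whose placements all fall inside one collapsed (IR-duplicated) gene
    placements: tuple[tuple[int, str], ...] = ()


class NaiveMapper:
    """Exact-seed (k-mer), ungapped read placement on a circular genome.

    Substitution-only by design: several seed offsets are tried per read so a
    sequencing error in one seed does not lose the placement; candidates are
    scored by full-length mismatch count, and a tie between distinct loci
    (e.g. reads from inside the IR) flags the read as multi-placed.
    """

    def __init__(self, genome: CircularGenome, k: int = 31,
                 max_mismatch_frac: float = 0.2):
        self.genome = genome
        self.k = k
        self.max_mismatch_frac = max_mismatch_frac
        L = len(genome)
        doubled = genome.seq + genome.seq[: k - 1]
        self.index: dict[str, list[int]] = {}
        for i in range(L):
            self.index.setdefault(doubled[i: i + k], []).append(i)

    def _candidates(self, seq: str) -> set[int]:
        L = len(self.genome)
        cands: set[int] = set()
        n_offsets = 0
        off = 0
        while off + self.k <= len(seq) and n_offsets < 4:
            for p in self.index.get(seq[off: off + self.k], ()):
                cands.add((p - off) % L)
            n_offsets += 1
            off += self.k
        if not cands:
            # densely mismatched read (e.g. many edited sites): slide the
            # seed to find any clean window before giving up
            for off in range(0, max(1, len(seq) - self.k + 1),
                             max(1, self.k // 4)):
                for p in self.index.get(seq[off: off + self.k], ()):
                    cands.add((p - off) % L)
                if cands:
                    break
        return cands

    def map_read(self, read: SeqRead) -> Alignment:
        L = len(self.genome)
        best: list[tuple[int, str]] = []  # (pos, strand)
        best_nm = None
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            if len(seq) < self.k:
                continue
            for pos in self._candidates(seq):
                ref = self.genome.fetch(pos, pos + len(seq))
                nm = sum(a != b for a, b in zip(seq, ref))
                if best_nm is None or nm < best_nm:
                    best_nm = nm
                    best = [(pos, strand)]
                elif nm == best_nm and (pos, strand) not in best:
                    best.append((pos, strand))
        if best_nm is None or best_nm > self.max_mismatch_frac * len(read.seq):
            return Alignment(read.name, -1, "+", read.seq, -1, "unaligned")
        # placements at the same locus on both strands count as distinct only
        # by position
        positions = {p for p, _ in best}
        pos, strand = best[0]
        status = "multi" if len(positions) > 1 else "unique"
        seq = read.seq if strand == "+" else revcomp(read.seq)
        return Alignment(read.name, pos, strand, seq, best_nm, status,
                         tuple(sorted(best)))


def naive_map(reads: list[SeqRead], genome: CircularGenome, k: int = 31,
              max_mismatch_frac: float = 0.2) -> list[Alignment]:
    """Map reads; unaligned/multi-placed reads are flagged, not dropped."""
    mapper = NaiveMapper(genome, k, max_mismatch_frac)
    return [mapper.map_read(r) for r in reads]


def write_sam(alignments: list[Alignment], genome: CircularGenome,
              path: str | Path) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": genome.id, "LN": len(genome)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id.replace(" ", "_")
            seg.query_sequence = a.seq
            if a.status == "unaligned":
                seg.is_unmapped = True
            else:
                seg.reference_id = 0
                seg.reference_start = a.pos % len(genome)
                seg.cigarstring = f"{len(a.seq)}M"
                seg.is_reverse = a.strand == "-"
                seg.mapping_quality = 0 if a.status == "multi" else 60
                seg.set_tag("NM", a.nm)
            fh.write(seg)


def read_sam(path: str | Path) -> list[Alignment]:
    """Load ungapped alignments from SAM; MAPQ 0 records are treated as
    multi-placed and excluded from pileups downstream."""
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out.append(Alignment(rec.query_name, -1, "+",
                                     rec.query_sequence or "", -1, "unaligned"))
                continue
            status = "multi" if rec.mapping_quality == 0 else "unique"
            out.append(Alignment(
                rec.query_name, rec.reference_start,
                "-" if rec.is_reverse else "+",
                rec.query_sequence or "",
                int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                status))
    return out


@dataclass
class GenePileup:
    """Sense-strand base counts per spliced CDS position of one gene."""

    gene_id: str
    cds_seq: str
    counts: np.ndarray  # (cds_len, 4) sense-strand A/C/G/T counts

    def depth(self, cds_pos: int) -> int:
        return int(self.counts[cds_pos - 1].sum())

    def base_count(self, cds_pos: int, base: str) -> int:
        return int(self.counts[cds_pos - 1, _BASE_IDX[base]])

    def column(self, cds_pos: int) -> "PileupColumn":
        return PileupColumn(self.gene_id, cds_pos,
                            self.cds_seq[cds_pos - 1],
                            tuple(int(x) for x in self.counts[cds_pos - 1]))


@dataclass(frozen=True)
class PileupColumn:
    """One strand-resolved CDS position (diagnostic view of a pileup)."""

    gene_id: str
    cds_pos: int
    ref_base: str
    counts: tuple[int, int, int, int]

    @property
    def depth(self) -> int:
        return sum(self.counts)


def build_pileup(alignments: list[Alignment], genome: CircularGenome,
                 annotations: list[GeneAnnotation],
                 ) -> dict[str, GenePileup]:
    """Per-base counts over annotated protein-coding CDS, re-oriented to each
    gene's sense strand; multi-placed and unaligned reads are excluded."""
    L = len(genome)
    pileups: dict[str, GenePileup] = {}
    pos_map: dict[int, list[tuple[str, int, str]]] = {}
    for g in annotations:
        if g.ftype != "protein":
            continue
        if g.genome_id and g.genome_id != genome.id:
            raise ValueError(f"annotation {g.gene_id} is for genome "
                             f"{g.genome_id!r}, not {genome.id!r}")
        cds = g.spliced_seq(genome)
        pileups[g.gene_id] = GenePileup(
            g.gene_id, cds, np.zeros((len(cds), 4), dtype=np.int64))
        for idx, gpos in enumerate(g.sense_positions(L)):
            pos_map.setdefault(gpos, []).append((g.gene_id, idx, g.strand))
    for a in alignments:
        if a.status != "unique":
            continue
        for off, base in enumerate(a.seq):
            if base not in _BASE_IDX:
                continue
            gpos = (a.pos + off) % L
            for gene_id, idx, strand in pos_map.get(gpos, ()):
                b = base if strand == "+" else complement(base)
                pileups[gene_id].counts[idx, _BASE_IDX[b]] += 1
    return pileups


@dataclass(frozen=True)
class EditingSite:
    gene_id: str
    cds_pos: int  # 1-based within the spliced CDS
    etype: str  # 'C2U' | 'U2C'
    depth: int
    edited: int
    rate: float
    codon_pos: int  # 1..3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    synonymous: bool

    @property
    def key(self) -> str:
        return f"{self.gene_id}-{self.cds_pos}"


def annotate_codon_effect(cds_seq: str, cds_pos: int, etype: str,
                          ) -> tuple[int, str, str, str, str, bool]:
    """Codon position and amino-acid effect of an edit at a CDS position.

    Translation uses the bacterial/plastid genetic code (NCBI table 11).
    Returns (codon_pos, ref_codon, edited_codon, ref_aa, edited_aa,
    synonymous).
    """
    n = len(cds_seq)
    if not 1 <= cds_pos <= n:
        raise ValueError(f"CDS position {cds_pos} outside CDS of {n} bp")
    if n % 3:
        warnings.warn(f"CDS length {n} not divisible by 3; trailing bases "
                      "ignored", stacklevel=2)
    codon_pos = (cds_pos - 1) % 3 + 1
    codon_start = cds_pos - codon_pos
    ref_codon = cds_seq[codon_start: codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"position {cds_pos} falls in an incomplete codon")
    new_base = {"C2U": "T", "U2C": "C"}[etype]
    edited_codon = (ref_codon[: codon_pos - 1] + new_base
                    + ref_codon[codon_pos:])
    ref_aa = str(Seq(ref_codon).translate(table=11))
    edited_aa = str(Seq(edited_codon).translate(table=11))
    return (codon_pos, ref_codon, edited_codon, ref_aa, edited_aa,
            ref_aa == edited_aa)


def call_editing_sites(pileups: dict[str, GenePileup], min_depth: int = 50,
                       min_rate: float = 0.05, min_edited_reads: int = 3,
                       ) -> list[EditingSite]:
    """C<->U transition sites passing coverage/rate/support filters.

    Only sense-strand C->T (C2U) and T->C (U2C) are editing; other mismatch
    classes are sequencing/mapping noise (see :func:`noise_profile`).
    """
    sites: list[EditingSite] = []
    for gene_id in sorted(pileups):
        pu = pileups[gene_id]
        for idx in range(len(pu.cds_seq)):
            ref = pu.cds_seq[idx]
            if ref == "C":
                etype, edited = "C2U", int(pu.counts[idx, _BASE_IDX["T"]])
            elif ref == "T":
                etype, edited = "U2C", int(pu.counts[idx, _BASE_IDX["C"]])
            else:
                continue
            depth = int(pu.counts[idx].sum())
            if depth < min_depth or edited < min_edited_reads:
                continue
            rate = edited / depth
            if rate < min_rate:
                continue
            cpos, rc_, ec_, ra, ea, syn = annotate_codon_effect(
                pu.cds_seq, idx + 1, etype)
            sites.append(EditingSite(gene_id, idx + 1, etype, depth, edited,
                                     rate, cpos, rc_, ec_, ra, ea, syn))
    return sites


def noise_profile(pileups: dict[str, GenePileup]) -> pd.DataFrame:
    """Counts of non-reference bases per substitution class (diagnostics;
    C->T and T->C are the editing channels, the rest is noise)."""
    classes: dict[str, int] = {}
    for pu in pileups.values():
        for idx, ref in enumerate(pu.cds_seq):
            if ref not in _BASE_IDX:
                continue
            for b in _IDX_BASE:
                if b == ref:
                    continue
                n = int(pu.counts[idx, _BASE_IDX[b]])
                if n:
                    classes[f"{ref}>{b}"] = classes.get(f"{ref}>{b}", 0) + n
    return (pd.DataFrame(sorted(classes.items()),
                         columns=["substitution", "reads"])
            if classes else pd.DataFrame(columns=["substitution", "reads"]))


@dataclass
class EditingComparison:
    site_key: str
    etype: str
    rates: dict[str, float | None]  # per line; None = not comparable
    changed: dict[str, bool | None]  # per non-reference line
    delta_pp: dict[str, float | None]


def _rate_at(pileups: dict[str, GenePileup], gene_id: str, cds_pos: int,
             etype: str, min_depth: int) -> float | None:
    pu = pileups.get(gene_id)
    if pu is None or not 1 <= cds_pos <= len(pu.cds_seq):
        return None
    depth = pu.depth(cds_pos)
    if depth < min_depth:
        return None
    edited = pu.base_count(cds_pos, "T" if etype == "C2U" else "C")
    return edited / depth


def compare_editing(sites_by_line: dict[str, list[EditingSite]],
                    pileups_by_line: dict[str, dict[str, GenePileup]],
                    reference: str, threshold_pp: float = 10.0,
                    min_depth: int = 50,
                    ) -> tuple[list[EditingComparison], pd.DataFrame]:
    """Cross-line comparison of editing rates against a reference line.

    The site universe is the union of called sites over lines. In a line
    where a site was not called, its rate is read from the pileup when
    coverage allows (an unedited covered site has rate 0); below ``min_depth``
    the site is not comparable there. A site is editing-rate-changed in a
    line when |rate - reference rate| exceeds ``threshold_pp`` absolute
    percentage points. Also returns the per-line summary (edited genes,
    edited sites, changed sites).
    """
    if reference not in sites_by_line:
        raise ValueError(f"reference line {reference!r} missing")
    lines = sorted(sites_by_line)
    universe: dict[str, tuple[str, int, str]] = {}
    for ln in lines:
        for s in sites_by_line[ln]:
            universe.setdefault(s.key, (s.gene_id, s.cds_pos, s.etype))
    comparisons: list[EditingComparison] = []
    for key in sorted(universe):
        gene_id, cds_pos, etype = universe[key]
        rates: dict[str, float | None] = {}
        for ln in lines:
            called = next((s for s in sites_by_line[ln] if s.key == key), None)
            if called is not None:
                rates[ln] = called.rate
            else:
                rates[ln] = _rate_at(pileups_by_line.get(ln, {}), gene_id,
                                     cds_pos, etype, min_depth)
        ref_rate = rates[reference]
        changed: dict[str, bool | None] = {}
        delta: dict[str, float | None] = {}
        for ln in lines:
            if ln == reference:
                continue
            if ref_rate is None or rates[ln] is None:
                changed[ln] = None
                delta[ln] = None
            else:
                d = 100.0 * (rates[ln] - ref_rate)
                delta[ln] = d
                changed[ln] = abs(d) > threshold_pp
        comparisons.append(EditingComparison(key, etype, rates, changed, delta))
    rows = []
    for ln in lines:
        called = sites_by_line[ln]
        n_changed = sum(1 for c in comparisons if c.changed.get(ln)) \
            if ln != reference else None
        rows.append({"line": ln,
                     "edited_genes": len({s.gene_id for s in called}),
                     "edited_sites": len(called),
                     "changed_sites_vs_reference": n_changed})
    summary = pd.DataFrame(rows)
    return comparisons, summary


def sites_table(sites: list[EditingSite], line_id: str = "") -> pd.DataFrame:
    rows = [{"line": line_id, "site": s.key, "gene": s.gene_id,
             "cds_pos": s.cds_pos, "type": s.etype, "depth": s.depth,
             "edited_reads": s.edited, "rate": round(s.rate, 4),
             "codon_pos": s.codon_pos, "ref_codon": s.ref_codon,
             "edited_codon": s.edited_codon, "ref_aa": s.ref_aa,
             "edited_aa": s.edited_aa, "synonymous": s.synonymous}
            for s in sites]
    return pd.DataFrame(rows)
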