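"""Synthetic plastomes, read populations and ground truth.

The generator emulates the system under study: a circular quadripartite
plastome (LSC + IRa + SSC + IRb, IRb the exact reverse complement of IRa)
carrying two-copy dispersed repeats with distinct flanks, a gene complement
of protein/tRNA/rRNA genes (some duplicated inside the IR), DNA long-read
populations in which a configurable fraction of molecules carry recombinant
repeat configurations, and RNA short reads with planted per-site editing
rates and per-gene expression levels. Every planted quantity is recorded in
a :class:`GroundTruth` manifest so downstream estimators can be scored
against known values.

Default dimensions follow the maternal rice plastome studied here: a
134,561 bp circle (LSC 80,572 / SSC 12,381 / IR 20,804 bp) at 39% GC with
110 genes (76 protein, 30 tRNA, 4 rRNA) and 8 two-copy dispersed repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CircularGenome, Interval, circular_gap, revcomp
from .io import SeqRead
from .structure import GeneAnnotation

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class EditingSpec:
    """A planted RNA-editing site: gene (by name), 1-based position within
    the spliced CDS, edit class and target per-transcript editing rate."""

    gene: str
    cds_pos: int
    etype: str  # 'C2U' | 'U2C'
    rate: float


@dataclass
class SimulationConfig:
    seed: int = 0
    # quadripartite dimensions (bp); defaults mirror the maternal rice line
    lsc_len: int = 80_572
    ssc_len: int = 12_381
    ir_len: int = 20_804
    gc: float = 0.39
    # dispersed two-copy repeats (all outside the IRs)
    n_repeats: int = 8
    repeat_len_range: tuple[int, int] = (25, 60)
    repeat_lengths: Sequence[int] | None = None
    repeat_orientations: Sequence[str] | None = None  # default alternating
    flank_len: int = 200
    recomb_fraction: float | Sequence[float] = 0.0  # per repeat
    # gene complement
    n_genes: int = 110
    n_ir_genes: int | None = None  # planted in IRa, hence present twice
    gene_len_range: tuple[int, int] = (150, 1200)
    gene_lengths: Sequence[int] | None = None
    min_gene_gap: int = 30
    # expression and editing (keyed by gene name)
    expression_levels: dict[str, float] | None = None
    editing_sites: Sequence[EditingSpec] | int = ()
    # read populations
    dna_read_len_range: tuple[int, int] = (1000, 3000)
    dna_depth: float = 20.0
    rna_read_len: int = 150
    rna_depth: float = 100.0
    error_rate: float = 0.001

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def recomb_fractions(self) -> list[float]:
        f = self.recomb_fraction
        fracs = [float(f)] * self.n_repeats if np.isscalar(f) else [float(x) for x in f]
        if len(fracs) != self.n_repeats:
            raise ConfigurationError(
                f"{len(fracs)} recombination fractions for {self.n_repeats} repeats")
        return fracs

    def validate(self) -> None:
        if self.lsc_len <= self.ssc_len:
            raise ConfigurationError("LSC must be larger than SSC")
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ConfigurationError("region lengths must be positive")
        if not 0 < self.gc < 1:
            raise ConfigurationError("gc must be in (0,1)")
        if self.repeat_lengths is None and self.repeat_len_range[0] <= 20:
            raise ConfigurationError("repeat lengths must exceed 20 bp")
        if self.repeat_lengths is not None and min(self.repeat_lengths, default=21) <= 20:
            raise ConfigurationError("repeat lengths must exceed 20 bp")
        fracs = self.recomb_fractions()
        if any(not 0 <= x < 1 for x in fracs):
            raise ConfigurationError("recomb_fraction must be in [0, 1)")
        if sum(fracs) >= 1:
            raise ConfigurationError("summed recombinant fractions must be < 1")
        if self.dna_read_len_range[1] > self.genome_length:
            raise ConfigurationError("DNA read length exceeds genome length")
        if isinstance(self.editing_sites, int):
            if self.editing_sites < 0:
                raise ConfigurationError("editing site count must be >= 0")
        else:
            for s in self.editing_sites:
                if not 0 <= s.rate <= 1:
                    raise ConfigurationError(f"editing rate {s.rate} outside [0,1]")
                if s.etype not in ("C2U", "U2C"):
                    raise ConfigurationError(f"unknown edit type {s.etype}")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ConfigurationError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class PlantedRepeat:
    repeat_id: str
    orientation: str
    unit_len: int
    copy1: Interval
    copy2: Interval
    recomb_fraction: float


@dataclass(frozen=True)
class PlantedEdit:
    gene: str
    cds_pos: int
    etype: str
    rate: float
    genome_pos: int


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring estimators."""

    genome_id: str
    seed: int
    genome_length: int
    regions: dict[str, Interval]
    repeats: list[PlantedRepeat]
    expression: dict[str, float]  # per gene name, relative abundance
    editing: list[PlantedEdit]

    def repeat(self, repeat_id: str) -> PlantedRepeat:
        for r in self.repeats:
            if r.repeat_id == repeat_id:
                return r
        raise KeyError(repeat_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [("genome", self.genome_id, "seed", str(self.seed)),
                ("genome", self.genome_id, "length", str(self.genome_length))]
        for name, iv in self.regions.items():
            rows.append(("region", name, "interval", f"{iv.start}-{iv.end}"))
        for r in self.repeats:
            rows.append(("repeat", r.repeat_id, "orientation", r.orientation))
            rows.append(("repeat", r.repeat_id, "unit_len", str(r.unit_len)))
            rows.append(("repeat", r.repeat_id, "copy1",
                         f"{r.copy1.start}-{r.copy1.end}"))
            rows.append(("repeat", r.repeat_id, "copy2",
                         f"{r.copy2.start}-{r.copy2.end}"))
            rows.append(("repeat", r.repeat_id, "recomb_fraction",
                         f"{r.recomb_fraction:.6g}"))
        for g, lv in self.expression.items():
            rows.append(("gene", g, "expression_level", f"{lv:.6g}"))
        for e in self.editing:
            rows.append(("editing", f"{e.gene}-{e.cds_pos}", "etype", e.etype))
            rows.append(("editing", f"{e.gene}-{e.cds_pos}", "rate", f"{e.rate:.6g}"))
            rows.append(("editing", f"{e.gene}-{e.cds_pos}", "genome_pos",
                         str(e.genome_pos)))
        return pd.DataFrame(rows, columns=["record", "id", "attribute", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    p = [at, gc / 2, gc / 2, at]
    return rng.choice(4, size=n, p=p)


def _seq_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _pack_region(rng: np.random.Generator, region_start: int, region_len: int,
                 lengths: list[int], min_gap: int) -> list[Interval]:
    """Place features of the given lengths in order with random gaps."""
    k = len(lengths)
    if k == 0:
        return []
    slack = region_len - sum(lengths) - (k + 1) * min_gap
    if slack < 0:
        raise ConfigurationError(
            f"infeasible packing: {sum(lengths)} bp of features + gaps exceed "
            f"region of {region_len} bp")
    extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1))
    out = []
    pos = region_start
    for i, ln in enumerate(lengths):
        pos += min_gap + int(extra[i])
        out.append(Interval(pos, pos + ln))
        pos += ln
    return out


def _gene_type_counts(n_genes: int) -> tuple[int, int, int]:
    """(protein, tRNA, rRNA) counts in roughly the 76:30:4 plastome ratio."""
    n_rrna = int(round(n_genes * 4 / 110))
    n_trna = int(round(n_genes * 30 / 110))
    n_prot = n_genes - n_rrna - n_trna
    if n_prot < 1:
        n_prot, n_trna, n_rrna = n_genes, 0, 0
    return n_prot, n_trna, n_rrna


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def generate_plastome(config: SimulationConfig,
                      ) -> tuple[CircularGenome, list[GeneAnnotation], GroundTruth]:
    """Build the genome, its annotation and the ground-truth manifest.

    The emitted circle is LSC + IRa + SSC + IRb with IRb the exact reverse
    complement of IRa. Repeats are planted as exact duplicated (direct) or
    reverse-complemented (inverted) segments in the single-copy regions,
    pairwise separated by more than one flank length; genes never overlap
    repeat units, so editing-site base forcing cannot corrupt a repeat copy.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    lsc0, ira0 = 0, config.lsc_len
    ssc0 = ira0 + config.ir_len
    irb0 = ssc0 + config.ssc_len
    regions = {"lsc": Interval(lsc0, ira0), "ira": Interval(ira0, ssc0),
               "ssc": Interval(ssc0, irb0), "irb": Interval(irb0, L)}

    codes = _random_seq(rng, config.lsc_len + config.ir_len + config.ssc_len,
                        config.gc)
    seq = list(_seq_str(codes))
    # mirror IRa into IRb
    seq.extend(revcomp("".join(seq[ira0:ssc0])))
    assert len(seq) == L

    # ---- genes ------------------------------------------------------------
    # default: 18 IR-duplicated gene names at full scale (the rice plastome's
    # two-copy genes), proportionally fewer on toy genomes
    n_ir_genes = config.n_ir_genes
    if n_ir_genes is None:
        n_ir_genes = 18 if config.n_genes >= 60 else config.n_genes // 6
    if n_ir_genes > config.n_genes:
        raise ConfigurationError("n_ir_genes exceeds n_genes")
    n_prot, n_trna, n_rrna = _gene_type_counts(config.n_genes)

    def draw_len(ftype: str) -> int:
        lo, hi = config.gene_len_range
        if ftype == "tRNA":
            return int(rng.integers(70, 91))
        if ftype == "rRNA":
            return int(rng.integers(1400, 2901))
        n = int(rng.integers(lo, hi + 1))
        return max(3, n - n % 3)  # protein CDS length divisible by 3

    specs: list[tuple[str, str]] = (
        [("protein", f"pg{i+1:03d}") for i in range(n_prot)]
        + [("tRNA", f"trn{i+1:02d}") for i in range(n_trna)]
        + [("rRNA", f"rrn{i+1:02d}") for i in range(n_rrna)])
    if config.gene_lengths is not None:
        if len(config.gene_lengths) != config.n_genes:
            raise ConfigurationError("gene_lengths length != n_genes")
        lengths = [int(x) for x in config.gene_lengths]
        lengths = [ln - ln % 3 if ft == "protein" else ln
                   for ln, (ft, _) in zip(lengths, specs)]
    else:
        lengths = [draw_len(ft) for ft, _ in specs]

    # IR genes: rRNAs first (the rRNA operon sits in the IR), then tRNAs
    order_ir_pref = sorted(range(config.n_genes),
                           key=lambda i: {"rRNA": 0, "tRNA": 1, "protein": 2}[specs[i][0]])
    ir_idx = set(order_ir_pref[:n_ir_genes])
    sc_idx = [i for i in range(config.n_genes) if i not in ir_idx]
    # split single-copy genes between LSC and SSC by capacity
    sc_perm = [sc_idx[k] for k in rng.permutation(len(sc_idx))]
    lsc_genes, ssc_genes, acc = [], [], 0
    ssc_budget = int(config.ssc_len * 0.7)
    for i in sc_perm:
        if acc + lengths[i] + config.min_gene_gap <= ssc_budget and len(ssc_genes) < len(sc_perm) // 4:
            ssc_genes.append(i)
            acc += lengths[i] + config.min_gene_gap
        else:
            lsc_genes.append(i)

    placements: dict[int, Interval] = {}
    for idxs, (rs, rl) in ((lsc_genes, (lsc0, config.lsc_len)),
                           (ssc_genes, (ssc0, config.ssc_len)),
                           (sorted(ir_idx), (ira0, config.ir_len))):
        ivs = _pack_region(rng, rs, rl, [lengths[i] for i in idxs],
                           config.min_gene_gap)
        for i, iv in zip(idxs, ivs):
            placements[i] = iv

    annotations: list[GeneAnnotation] = []
    gene_strand: dict[str, str] = {}
    for i, (ftype, name) in enumerate(specs):
        iv = placements[i]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_strand[name] = strand
        if i in ir_idx:
            annotations.append(GeneAnnotation(f"{name}-1", name, ftype, strand,
                                              (iv,)))
            # mirrored copy in IRb, on the opposite strand
            m_start = irb0 + (ssc0 - iv.end)
            m_iv = Interval(m_start, m_start + len(iv))
            m_strand = "-" if strand == "+" else "+"
            annotations.append(GeneAnnotation(f"{name}-2", name, ftype,
                                              m_strand, (m_iv,)))
        else:
            annotations.append(GeneAnnotation(name, name, ftype, strand, (iv,)))

    # ---- repeats ----------------------------------------------------------
    fracs = config.recomb_fractions()
    if config.repeat_lengths is not None:
        if len(config.repeat_lengths) != config.n_repeats:
            raise ConfigurationError("repeat_lengths length != n_repeats")
        rep_lens = [int(x) for x in config.repeat_lengths]
    else:
        lo, hi = config.repeat_len_range
        rep_lens = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_repeats)]
    if config.repeat_orientations is not None:
        orients = list(config.repeat_orientations)
        if len(orients) != config.n_repeats:
            raise ConfigurationError("repeat_orientations length != n_repeats")
    else:
        orients = ["direct" if k % 2 == 0 else "inverted"
                   for k in range(config.n_repeats)]

    gene_ivs = sorted((placements[i] for i in range(config.n_genes)),
                      key=lambda iv: iv.start)
    margin = config.flank_len + 10
    free: list[tuple[int, int]] = []  # gaps in single-copy regions
    for rs, re_ in ((lsc0 + margin, ira0 - margin), (ssc0 + margin, irb0 - margin)):
        pos = rs
        for giv in gene_ivs:
            if giv.end <= rs or giv.start >= re_:
                continue
            if giv.start > pos:
                free.append((pos, giv.start))
            pos = max(pos, giv.end)
        if re_ > pos:
            free.append((pos, re_))

    placed_units: list[Interval] = []
    # a read must never span both junctions of one repeat, so the two copies
    # sit more than one maximal read length apart
    min_copy_sep = max(margin, config.dna_read_len_range[1])

    def place_unit(ulen: int, apart_from: Interval | None = None) -> Interval:
        for _attempt in range(2000):
            g = free[int(rng.integers(0, len(free)))]
            if g[1] - g[0] < ulen:
                continue
            s = int(rng.integers(g[0], g[1] - ulen + 1))
            iv = Interval(s, s + ulen)
            ok = True
            for u in placed_units:
                if iv.start < u.end + margin and u.start - margin < iv.end:
                    ok = False
                    break
            if ok and apart_from is not None and \
                    circular_gap(iv, apart_from, L) <= min_copy_sep:
                ok = False
            if ok:
                placed_units.append(iv)
                return iv
        raise ConfigurationError("could not place repeat copies; regions too "
                                 "crowded for the requested repeats")

    repeats: list[PlantedRepeat] = []
    for k in range(config.n_repeats):
        ulen = rep_lens[k]
        unit = _seq_str(_random_seq(rng, ulen, config.gc))
        c1 = place_unit(ulen)
        c2 = place_unit(ulen, apart_from=c1)
        if c2.start < c1.start:
            c1, c2 = c2, c1
        seq[c1.start:c1.end] = list(unit)
        seq[c2.start:c2.end] = list(unit if orients[k] == "direct"
                                    else revcomp(unit))
        repeats.append(PlantedRepeat(f"R{k+1}", orients[k], ulen, c1, c2,
                                     fracs[k]))
    repeats.sort(key=lambda r: r.copy1.start)
    repeats = [replace(r, repeat_id=f"R{k+1}") for k, r in enumerate(repeats)]

    # ---- expression levels -------------------------------------------------
    names = [name for _, name in specs]
    expression = {n: 1.0 for n in names}
    if config.expression_levels:
        unknown = set(config.expression_levels) - set(names)
        if unknown:
            raise ConfigurationError(f"expression levels for unknown genes: "
                                     f"{sorted(unknown)}")
        expression.update({k: float(v) for k, v in config.expression_levels.items()})

    # ---- editing sites -----------------------------------------------------
    protein_sc = [name for i, (ft, name) in enumerate(specs)
                  if ft == "protein" and i not in ir_idx]
    name_to_idx = {name: i for i, (_, name) in enumerate(specs)}
    if isinstance(config.editing_sites, int):
        sites: list[EditingSpec] = []
        n_auto = config.editing_sites
        for j in range(n_auto):
            gname = protein_sc[int(rng.integers(0, len(protein_sc)))]
            glen = lengths[name_to_idx[gname]]
            pos = int(rng.integers(1, glen + 1))
            etype = "C2U" if rng.random() < 52 / 74 else "U2C"
            rate = float(np.round(rng.uniform(0.1, 1.0), 3))
            sites.append(EditingSpec(gname, pos, etype, rate))
        # one site per (gene, pos)
        seen: set[tuple[str, int]] = set()
        sites = [s for s in sites
                 if (s.gene, s.cds_pos) not in seen
                 and not seen.add((s.gene, s.cds_pos))]
    else:
        sites = list(config.editing_sites)

    planted_edits: list[PlantedEdit] = []
    for s in sites:
        i = name_to_idx.get(s.gene)
        if i is None:
            raise ConfigurationError(f"editing site in unknown gene {s.gene!r}")
        if specs[i][0] != "protein":
            raise ConfigurationError(
                f"editing site {s.gene}-{s.cds_pos} is outside any CDS "
                f"({specs[i][0]} gene)")
        if i in ir_idx:
            raise ConfigurationError(
                f"editing sites in IR-duplicated genes are not supported "
                f"({s.gene})")
        iv = placements[i]
        if not 1 <= s.cds_pos <= len(iv):
            raise ConfigurationError(
                f"editing site {s.gene}-{s.cds_pos} beyond CDS of {len(iv)} bp")
        strand = gene_strand[s.gene]
        if strand == "+":
            gpos = iv.start + s.cds_pos - 1
        else:
            gpos = iv.end - s.cds_pos
        sense_base = "C" if s.etype == "C2U" else "T"
        seq[gpos] = sense_base if strand == "+" else revcomp(sense_base)
        planted_edits.append(PlantedEdit(s.gene, s.cds_pos, s.etype,
                                         float(s.rate), gpos))

    # break chance extensions so maximal matches end exactly at planted
    # boundaries (the IR pair and every repeat copy pair)
    forced = {e.genome_pos for e in planted_edits}

    def break_pair(p: int, q: int, want_comp: bool) -> None:
        """Ensure seq[p] != seq[q] (direct pairing) or != comp(seq[q])."""
        f = (lambda b: revcomp(b)) if want_comp else (lambda b: b)
        if seq[p] != f(seq[q]):
            return
        pos = p if p not in forced else q
        if pos in forced:
            raise ConfigurationError(
                "editing site collides with a repeat/IR boundary; re-seed")
        avoid = f(seq[q]) if pos == p else f(seq[p])
        seq[pos] = "A" if avoid != "A" else "C"

    break_pair(ira0 - 1, 0, want_comp=True)  # IR left edge vs LSC start
    break_pair(ssc0, irb0 - 1, want_comp=True)  # IR right edge inside SSC
    for r in repeats:
        s1, e1 = r.copy1.start, r.copy1.end
        s2, e2 = r.copy2.start, r.copy2.end
        if r.orientation == "direct":
            break_pair(s1 - 1, s2 - 1, want_comp=False)
            break_pair(e1, e2, want_comp=False)
        else:
            break_pair(s1 - 1, e2, want_comp=True)
            break_pair(e1, s2 - 1, want_comp=True)

    genome = CircularGenome(f"synth-plastome-seed{config.seed}", "".join(seq))

    # flank distinctness check (unambiguous configurations on clean data)
    for r in repeats:
        fl = config.flank_len
        a = genome.fetch(r.copy1.start - fl, r.copy1.start)
        b = genome.fetch(r.copy1.end, r.copy1.end + fl)
        if r.orientation == "direct":
            c = genome.fetch(r.copy2.start - fl, r.copy2.start)
            d = genome.fetch(r.copy2.end, r.copy2.end + fl)
        else:
            c = revcomp(genome.fetch(r.copy2.end, r.copy2.end + fl))
            d = revcomp(genome.fetch(r.copy2.start - fl, r.copy2.start))
        flanks = [a, b, c, d]
        for x in range(4):
            for y in range(x + 1, 4):
                if _identity(flanks[x], flanks[y]) >= 0.6:
                    raise ConfigurationError(
                        f"{r.repeat_id}: flank pair identity >= 60%; "
                        "re-seed or relocate repeats")

    truth = GroundTruth(genome_id=genome.id, seed=config.seed,
                        genome_length=L, regions=regions, repeats=repeats,
                        expression=expression, editing=planted_edits)
    for g in annotations:
        g.genome_id = genome.id
    return genome, annotations, truth


# ---------------------------------------------------------------------------
# DNA long reads with repeat-mediated recombination
# ---------------------------------------------------------------------------

@dataclass
class _Molecule:
    seq: str
    # (repeat_id, configuration label, unit start in molecule coords, unit len)
    junctions: list[tuple[str, str, int, int]]


def _shift_junctions(juncs, offset: int, mol_len: int):
    return [(rid, lab, (s - offset) % mol_len, ln) for rid, lab, s, ln in juncs]


def _molecule_pools(genome: CircularGenome,
                    truth: GroundTruth) -> tuple[list[float], list[list[_Molecule]]]:
    """Parental pool plus one recombinant pool per repeat with f > 0.

    A recombinant molecule carries exactly one crossover. For a direct repeat
    the crossover resolves the circle into two smaller circles (junctions
    a-R-d and c-R-b split between them); for an inverted repeat it inverts
    the segment between the copies in place. Copies of *other* repeats keep
    their parental local context in every product, so their junctions stay
    parental.
    """
    S = genome.seq
    L = len(S)
    parental_junc = []
    for r in truth.repeats:
        parental_junc.append((r.repeat_id, "ab", r.copy1.start, r.unit_len))
        parental_junc.append((r.repeat_id, "cd", r.copy2.start, r.unit_len))
    pools = [[_Molecule(S, parental_junc)]]
    weights = []
    for r in truth.repeats:
        if r.recomb_fraction <= 0:
            continue
        s1, e1 = r.copy1.start, r.copy1.end
        s2, e2 = r.copy2.start, r.copy2.end
        if r.orientation == "direct":
            # circle A = S[e1:e2] (copy2 + middle), junction c-R-b at copy2
            segA = S[e1:e2]
            juncA = [(r.repeat_id, "cb", s2 - e1, r.unit_len)]
            # circle B = S[e2:] + S[:e1] (copy1 + the rest), junction a-R-d
            segB = S[e2:] + S[:e1]
            juncB = [(r.repeat_id, "ad", (s1 - e2) % L, r.unit_len)]
            for o in truth.repeats:
                if o.repeat_id == r.repeat_id:
                    continue
                for lab, iv in (("ab", o.copy1), ("cd", o.copy2)):
                    if e1 <= iv.start and iv.end <= e2:
                        juncA.append((o.repeat_id, lab, iv.start - e1, o.unit_len))
                    else:
                        juncB.append((o.repeat_id, lab,
                                      (iv.start - e2) % L, o.unit_len))
            pools.append([_Molecule(segA, juncA), _Molecule(segB, juncB)])
        else:
            # single circle with the inter-copy segment inverted
            seg = S[:e1] + revcomp(S[e1:s2]) + S[s2:]
            junc = [(r.repeat_id, "ad", s1, r.unit_len),
                    (r.repeat_id, "cb", s2, r.unit_len)]
            for o in truth.repeats:
                if o.repeat_id == r.repeat_id:
                    continue
                for lab, iv in (("ab", o.copy1), ("cd", o.copy2)):
                    if e1 <= iv.start and iv.end <= s2:
                        junc.append((o.repeat_id, lab,
                                     e1 + s2 - iv.end, o.unit_len))
                    else:
                        junc.append((o.repeat_id, lab, iv.start, o.unit_len))
            pools.append([_Molecule(seg, junc)])
        weights.append(r.recomb_fraction)
    weights.insert(0, 1.0 - sum(weights))
    return weights, pools


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        old = out[i]
        choices = [b for b in "ACGT" if b != old]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _circ_sub(seq: str, start: int, n: int) -> str:
    L = len(seq)
    s = start % L
    e = s + n
    if e <= L:
        return seq[s:e]
    return seq[s:] + seq[: e - L]


def simulate_dna_reads(genome: CircularGenome, truth: GroundTruth,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> list[SeqRead]:
    """Single-end long reads from a population of parental and recombinant
    molecules; each read's name records its source pool and every repeat
    junction it fully spans (with flank coverages), for truth-based scoring.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.dna_read_len_range
    if hi > len(genome):
        raise ConfigurationError("DNA read length exceeds genome length")
    weights, pools = _molecule_pools(genome, truth)
    n_reads = int(round(config.dna_depth * len(genome) / ((lo + hi) / 2)))
    pool_draw = rng.random(n_reads)
    cum = np.cumsum(weights)
    read_lens = rng.integers(lo, hi + 1, size=n_reads)
    strand_draw = rng.random(n_reads) < 0.5
    start_draw = rng.random(n_reads)
    reads: list[SeqRead] = []
    for i in range(n_reads):
        pool_i = int(np.searchsorted(cum, pool_draw[i], side="right"))
        pool_i = min(pool_i, len(pools) - 1)
        mols = pools[pool_i]
        if len(mols) == 1:
            mol_i = 0
        else:  # sample molecule proportional to its length
            tot = sum(len(m.seq) for m in mols)
            mol_i = 0 if start_draw[i] * tot < len(mols[0].seq) else 1
        mol = mols[mol_i]
        mlen = len(mol.seq)
        rlen = int(min(read_lens[i], mlen))
        start = int(rng.integers(0, mlen))
        raw = _circ_sub(mol.seq, start, rlen)
        jx_parts = []
        for rid, lab, js, jlen in mol.junctions:
            rel = (js - start) % mlen
            lcov = rel
            rcov = rlen - rel - jlen
            if rel + jlen <= rlen and lcov > 0 and rcov > 0:
                jx_parts.append(f"{rid}:{lab}:{lcov}:{rcov}")
        strand = "-" if strand_draw[i] else "+"
        if strand == "-":
            raw = revcomp(raw)
        raw = _apply_errors(rng, raw, config.error_rate)
        pool_name = "parental" if pool_i == 0 else \
            [r.repeat_id for r in truth.repeats if r.recomb_fraction > 0][pool_i - 1]
        name = (f"dr{i:06d};pool={pool_name};mol={mol_i};start={start};"
                f"len={rlen};strand={strand};jx={'+'.join(jx_parts) or '-'}")
        reads.append(SeqRead(name, raw))
    return reads


# ---------------------------------------------------------------------------
# RNA reads with planted editing and expression
# ---------------------------------------------------------------------------

def simulate_rna_reads(genome: CircularGenome,
                       annotations: list[GeneAnnotation], truth: GroundTruth,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> list[SeqRead]:
    """Single-end RNA reads from spliced sense-strand transcripts.

    Genes are sampled proportionally to ``expression_level x transcript
    length`` (so equal-length genes yield read counts in the ratio of their
    levels); each transcript copy carries a planted edit independently with
    probability equal to the site's target rate; substitution errors follow.
    IR-duplicated genes are transcribed once per gene name.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    by_name: dict[str, GeneAnnotation] = {}
    for g in annotations:
        by_name.setdefault(g.name, g)
    names = sorted(by_name)
    transcripts = {n: by_name[n].spliced_seq(genome) for n in names}
    levels = np.array([truth.expression.get(n, 1.0) for n in names])
    tlens = np.array([len(transcripts[n]) for n in names])
    weights = levels * tlens
    p = weights / weights.sum()
    edits_by_gene: dict[str, list[PlantedEdit]] = {}
    for e in truth.editing:
        edits_by_gene.setdefault(e.gene, []).append(e)
    total_len = int(tlens.sum())
    n_reads = int(round(config.rna_depth * total_len / config.rna_read_len))
    gene_draw = rng.choice(len(names), size=n_reads, p=p)
    start_draw = rng.random(n_reads)
    strand_draw = rng.random(n_reads) < 0.5
    reads: list[SeqRead] = []
    for i in range(n_reads):
        name = names[int(gene_draw[i])]
        t = transcripts[name]
        rlen = min(config.rna_read_len, len(t))
        start = int(start_draw[i] * (len(t) - rlen + 1))
        raw = t[start:start + rlen]
        edited_at = []
        for e in edits_by_gene.get(name, ()):
            off = e.cds_pos - 1 - start
            if 0 <= off < rlen and rng.random() < e.rate:
                base = "T" if e.etype == "C2U" else "C"
                raw = raw[:off] + base + raw[off + 1:]
                edited_at.append(str(e.cds_pos))
        strand = "-" if strand_draw[i] else "+"
        if strand == "-":
            raw = revcomp(raw)
        raw = _apply_errors(rng, raw, config.error_rate)
        rname = (f"rr{i:06d};gene={name};start={start};len={rlen};"
                 f"strand={strand};ed={','.join(edited_at) or '-'}")
        reads.append(SeqRead(rname, raw))
    return reads
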