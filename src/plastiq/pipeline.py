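"""End-to-end orchestration: structure -> repeats -> recombination ->
editing -> expression -> line-vs-maternal comparison.

All stage outputs are TSV files under one output directory; re-running with
identical inputs and configuration is bit-identical (checksums are written
alongside). The maternal line supplies the reference genome, repeat set and
the denominators for relative content / relative expression / editing-rate
change calls.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import editscan, exprquant, io, recombquant, repeatscan, structure, synthio
from .genome import Interval

logger = logging.getLogger("plastiq")

STAGES = ("structure", "repeats", "recomb", "editing", "expression")
_DEPS = {"structure": (), "repeats": ("structure",),
         "recomb": ("structure", "repeats"),
         "editing": ("structure",), "expression": ("structure", "repeats")}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class LineInputs:
    genome: str | Path
    gff: str | Path
    dna_reads: str | Path | None = None
    rna_reads: str | Path | None = None
    rna_sam: str | Path | None = None


@dataclass
class RunConfig:
    lines: dict[str, LineInputs]
    maternal: str
    outdir: str | Path
    min_ir_len: int = 1000
    word_size: int = 20
    min_len: int = 21
    min_identity: float = 1.0
    flank_len: int = 200
    min_anchor: int = 50
    max_mismatch_frac: float = 0.1
    min_depth: int = 50
    min_rate: float = 0.05
    min_edited_reads: int = 3
    threshold_pp: float = 10.0
    window: int = 2000

    def validate(self) -> None:
        if self.maternal not in self.lines:
            raise ValueError(f"maternal line {self.maternal!r} not among "
                             f"lines {sorted(self.lines)}")
        if not self.lines:
            raise ValueError("no lines configured")


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _load_reads(path: str | Path) -> list[io.SeqRead]:
    p = str(path)
    if p.endswith((".fa", ".fasta")):
        return io.read_fasta_reads(p)
    return io.read_fastq(p)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages (dependencies are pulled in) and write
    per-stage TSVs; returns the in-memory results bundle."""
    config.validate()
    want: set[str] = set()

    def need(s: str) -> None:
        if s in want:
            return
        want.add(s)
        for d in _DEPS[s]:
            need(d)

    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        need(s)
    ordered = [s for s in STAGES if s in want]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("stages: %s", ",".join(ordered))
    for k, v in sorted(vars(config).items()):
        if k not in ("lines",):
            logger.info("config %s = %s", k, v)
    results: dict = {}
    for stage in ordered:
        try:
            _STAGE_FUNCS[stage](config, outdir, results)
        except Exception as exc:  # noqa: BLE001 - re-raised stage-tagged
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineError(stage, exc) from exc
    checks = output_checksums(outdir)
    _write(pd.DataFrame(sorted(checks.items()), columns=["file", "sha256"]),
           outdir / "checksums.tsv")
    return results


def _setup_logging(outdir: Path) -> None:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[plastiq] %(levelname)s %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    logfile = outdir / "pipeline.log"
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)


def _stage_structure(config: RunConfig, outdir: Path, results: dict) -> None:
    genomes, annots, structures = {}, {}, {}
    rows = []
    for line in sorted(config.lines):
        inp = config.lines[line]
        g = io.read_fasta_genome(inp.genome)
        a = io.read_gff3(inp.gff)
        st = structure.detect_quadripartite(g, config.min_ir_len)
        genomes[line], annots[line], structures[line] = g, a, st
        rows.append(structure.structure_table_row(line, g, a, st))
        logger.info("structure %s: L=%d IR=%d LSC=%d SSC=%d", line, len(g),
                    st.ir_size, st.lsc_size, st.ssc_size)
    _write(pd.DataFrame(rows), outdir / "structure_summary.tsv")
    diff_rows = []
    mat = config.maternal
    for line in sorted(config.lines):
        if line == mat:
            continue
        for d in structure.compare_gene_order(annots[mat], annots[line]):
            diff_rows.append({"line": line, "gene": d.gene_id, "kind": d.kind})
    _write(pd.DataFrame(diff_rows, columns=["line", "gene", "kind"]),
           outdir / "gene_order_diffs.tsv")
    results.update(genomes=genomes, annotations=annots, structures=structures)


def _stage_repeats(config: RunConfig, outdir: Path, results: dict) -> None:
    mat = config.maternal
    genome = results["genomes"][mat]
    st = results["structures"][mat]
    reduced, offset = repeatscan.excise_ir(genome, st)
    scan = repeatscan.find_repeats(reduced, config.word_size, config.min_len,
                                   config.min_identity)
    L_full = len(genome)

    def to_full(iv: Interval) -> Interval:
        s = (iv.start + offset) % L_full
        return Interval(s, s + len(iv))

    full_copies = {t.repeat_id: (to_full(t.copy1), to_full(t.copy2))
                   for t in scan.types}
    configs = {}
    rows = []
    junction_rows = []
    all_copies = [iv for t in scan.types for iv in (t.copy1, t.copy2)]
    for t in scan.types:
        cfg = repeatscan.enumerate_configurations(
            t, reduced, config.flank_len, config.min_anchor,
            other_copies=all_copies)
        configs[t.repeat_id] = cfg
        rows.append({
            "repeat": t.repeat_id, "orientation": t.orientation,
            "length": t.length, "identity": round(t.identity, 4),
            "copy1_start": t.copy1.start + 1, "copy1_end": t.copy1.end,
            "copy2_start": t.copy2.start + 1, "copy2_end": t.copy2.end})
        for lab, c in sorted(cfg.items()):
            junction_rows.append({"repeat": t.repeat_id, "configuration": lab,
                                  "class": c.configuration_class,
                                  "junction": c.junction})
    _write(pd.DataFrame(rows), outdir / "repeats.tsv")
    _write(pd.DataFrame(junction_rows), outdir / "repeat_junctions.tsv")
    cov = repeatscan.repeat_coverage(scan, reduced)
    # proximity on the full circle
    fake_types = [replace(t, copy1=full_copies[t.repeat_id][0],
                          copy2=full_copies[t.repeat_id][1])
                  for t in scan.types]
    rep_flags, gene_flags = repeatscan.repeats_near_genes(
        fake_types, results["annotations"][mat], L_full, config.window)
    _write(pd.DataFrame(
        [{"repeat": k, "near_gene": v} for k, v in sorted(rep_flags.items())]),
        outdir / "repeat_gene_proximity.tsv")
    logger.info("repeats: %d two-copy types, %d families, coverage %.2f%%",
                len(scan.types), len(scan.families), cov)
    results.update(repeat_scan=scan, repeat_configs=configs,
                   repeat_coverage_pct=cov, repeat_flags=rep_flags,
                   gene_repeat_flags=gene_flags)


def _stage_recomb(config: RunConfig, outdir: Path, results: dict) -> None:
    configs = results["repeat_configs"]
    per_line: dict[str, dict[str, recombquant.ConfigurationCounts]] = {}
    for line in sorted(config.lines):
        inp = config.lines[line]
        if inp.dna_reads is None:
            logger.info("recomb %s: no DNA reads provided, skipped", line)
            continue
        reads = _load_reads(inp.dna_reads)
        per_line[line] = {}
        for rid, cfg in sorted(configs.items()):
            cc = recombquant.count_configurations(
                reads, cfg, line, config.min_anchor, config.max_mismatch_frac)
            per_line[line][rid] = cc
        logger.info("recomb %s: %d reads classified over %d repeats", line,
                    len(reads), len(configs))
    rows = []
    mat = config.maternal
    for line in sorted(per_line):
        for rid, cc in sorted(per_line[line].items()):
            contents = cc.contents or dict.fromkeys(recombquant.LABELS, None)
            rels = (recombquant.relative_content(cc, per_line[mat][rid])
                    if mat in per_line else [])
            rel_by_lab = {r.label: r.relative_pct for r in rels}
            for lab in recombquant.LABELS:
                rows.append({
                    "line": line, "repeat": rid, "configuration": lab,
                    "reads": cc.counts[lab], "ambiguous_reads": cc.ambiguous,
                    "content": contents[lab],
                    "relative_content_pct": rel_by_lab.get(lab),
                    "recombination_rate": cc.recombination_rate})
    _write(pd.DataFrame(rows), outdir / "recombination.tsv")
    if per_line:
        table = recombquant.recombination_rate_table(per_line)
        table.reset_index().to_csv(outdir / "recombination_rate_matrix.tsv",
                                   sep="\t", index=False, float_format="%.6g")
    results["configuration_counts"] = per_line


def _rna_alignments(config: RunConfig, line: str,
                    results: dict) -> list[editscan.Alignment] | None:
    inp = config.lines[line]
    mat_genome = results["genomes"][config.maternal]
    if inp.rna_sam is not None:
        return editscan.read_sam(inp.rna_sam)
    if inp.rna_reads is None:
        return None
    cache = results.setdefault("_rna_aln", {})
    if line not in cache:
        reads = _load_reads(inp.rna_reads)
        mapper = results.get("_rna_mapper")
        if mapper is None:
            mapper = editscan.NaiveMapper(mat_genome)
            results["_rna_mapper"] = mapper
        cache[line] = [mapper.map_read(r) for r in reads]
        logger.info("mapped %d RNA reads for %s", len(reads), line)
    return cache[line]


def _stage_editing(config: RunConfig, outdir: Path, results: dict) -> None:
    mat = config.maternal
    genome = results["genomes"][mat]
    annots = results["annotations"][mat]
    sites_by_line, pileups_by_line = {}, {}
    tables = []
    for line in sorted(config.lines):
        aln = _rna_alignments(config, line, results)
        if aln is None:
            logger.info("editing %s: no RNA input, skipped", line)
            continue
        pu = editscan.build_pileup(aln, genome, annots)
        sites = editscan.call_editing_sites(pu, config.min_depth,
                                            config.min_rate,
                                            config.min_edited_reads)
        sites_by_line[line], pileups_by_line[line] = sites, pu
        tables.append(editscan.sites_table(sites, line))
        logger.info("editing %s: %d sites in %d genes", line, len(sites),
                    len({s.gene_id for s in sites}))
    if tables:
        _write(pd.concat(tables, ignore_index=True),
               outdir / "editing_sites.tsv")
    if mat in sites_by_line:
        comps, summary = editscan.compare_editing(
            sites_by_line, pileups_by_line, mat, config.threshold_pp,
            config.min_depth)
        lines = sorted(sites_by_line)
        mat_rows = []
        for c in comps:
            row = {"site": c.site_key, "type": c.etype}
            for ln in lines:
                row[f"rate_{ln}"] = c.rates.get(ln)
                if ln != mat:
                    row[f"changed_{ln}"] = c.changed.get(ln)
            mat_rows.append(row)
        _write(pd.DataFrame(mat_rows), outdir / "editing_comparison.tsv")
        _write(summary, outdir / "editing_summary.tsv")
        results.update(editing_comparisons=comps, editing_summary=summary)
    results.update(editing_sites=sites_by_line, pileups=pileups_by_line)


def _stage_expression(config: RunConfig, outdir: Path, results: dict) -> None:
    mat = config.maternal
    annots = results["annotations"][mat]
    L = len(results["genomes"][mat])
    gene_flags = results.get("gene_repeat_flags", {})
    name_flags: dict[str, bool] = {}
    for g in annots:
        name_flags[g.name] = name_flags.get(g.name, False) or \
            gene_flags.get(g.gene_id, False)
    tables = {}
    for line in sorted(config.lines):
        aln = _rna_alignments(config, line, results)
        if aln is None:
            logger.info("expression %s: no RNA input, skipped", line)
            continue
        tables[line] = exprquant.expression_table(aln, annots, L, line,
                                                  name_flags)
    if tables:
        _write(pd.concat(tables.values(), ignore_index=True),
               outdir / "expression.tsv")
    rel_rows = []
    summaries = {}
    for line in sorted(tables):
        if line == mat or mat not in tables:
            continue
        joined, summary = exprquant.relative_expression(tables[line],
                                                        tables[mat])
        summaries[line] = summary
        for _, r in joined.iterrows():
            rel_rows.append({
                "line": line, "gene": r["gene"], "count": r["count_bil"],
                "fpkm": r["fpkm_bil"], "fpkm_maternal": r["fpkm_mat"],
                "ratio": r["ratio"], "down": r["down"], "up": r["up"],
                "repeat_proximal": r["repeat_proximal_bil"]})
    _write(pd.DataFrame(rel_rows), outdir / "relative_expression.tsv")
    results.update(expression_tables=tables, expression_summaries=summaries)


_STAGE_FUNCS = {"structure": _stage_structure, "repeats": _stage_repeats,
                "recomb": _stage_recomb, "editing": _stage_editing,
                "expression": _stage_expression}


def output_checksums(outdir: Path) -> dict[str, str]:
    """SHA-256 of every TSV output (the determinism contract)."""
    out = {}
    for p in sorted(Path(outdir).glob("*.tsv")):
        if p.name == "checksums.tsv":
            continue
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# Synthetic multi-line datasets
# ---------------------------------------------------------------------------

@dataclass
class LineSpec:
    """Per-line deviations from the shared (maternal) simulation: each line
    shares the genome and editing-site positions but may have its own
    recombinant fractions, per-site editing rates and expression levels."""

    recomb_fraction: float | list[float] | None = None
    editing_rates: dict[str, float] = field(default_factory=dict)  # "gene-pos"
    expression_levels: dict[str, float] = field(default_factory=dict)


def simulate_dataset(outdir: str | Path, base: synthio.SimulationConfig,
                     line_specs: dict[str, LineSpec],
                     ) -> tuple[dict[str, LineInputs], synthio.GroundTruth]:
    """Generate one shared plastome plus per-line DNA/RNA read sets.

    Returns pipeline-ready inputs and the maternal ground truth; per-line
    truths are written as TSV manifests next to the reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotations, truth = synthio.generate_plastome(base)
    gpath = outdir / "genome.fasta"
    apath = outdir / "annotation.gff3"
    io.write_fasta(genome, gpath)
    io.write_gff3(annotations, genome, apath)
    lines: dict[str, LineInputs] = {}
    for k, (line, spec) in enumerate(sorted(line_specs.items())):
        fr = spec.recomb_fraction
        if fr is None:
            repeats = truth.repeats
        else:
            fracs = ([float(fr)] * len(truth.repeats) if np.isscalar(fr)
                     else [float(x) for x in fr])
            repeats = [replace(r, recomb_fraction=f)
                       for r, f in zip(truth.repeats, fracs)]
        editing = [replace(e, rate=spec.editing_rates.get(
            f"{e.gene}-{e.cds_pos}", e.rate)) for e in truth.editing]
        expression = dict(truth.expression)
        expression.update(spec.expression_levels)
        ltruth = replace(truth, repeats=repeats, editing=editing,
                         expression=expression)
        lconfig = replace(base, recomb_fraction=[r.recomb_fraction
                                                 for r in repeats])
        rng_dna = np.random.default_rng(
            np.random.SeedSequence([base.seed, 101 + k]))
        rng_rna = np.random.default_rng(
            np.random.SeedSequence([base.seed, 201 + k]))
        dna = synthio.simulate_dna_reads(genome, ltruth, lconfig, rng_dna)
        rna = synthio.simulate_rna_reads(genome, annotations, ltruth,
                                         lconfig, rng_rna)
        dpath = outdir / f"{line}.dna.fastq"
        rpath = outdir / f"{line}.rna.fastq"
        io.write_fastq(dna, dpath)
        io.write_fastq(rna, rpath)
        ltruth.to_tsv(outdir / f"{line}.truth.tsv")
        lines[line] = LineInputs(genome=gpath, gff=apath, dna_reads=dpath,
                                 rna_reads=rpath)
    return lines, truth
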