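"""Per-gene expression from RNA alignments: counts, FPKM, relative levels.

Plastid genes are single-isoform, so read-to-gene assignment is a simple
overlap majority rule rather than a full transcript-abundance model: a read
belongs to the gene covering the largest share of its aligned bases, provided
that share is at least half the read. Genes duplicated between the two IR
copies cannot be told apart by their reads and are collapsed under one gene
name before counting. Relative expression is FPKM in a derived line over
FPKM in the maternal line.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .editscan import Alignment
from .structure import GeneAnnotation


@dataclass(frozen=True)
class ExpressionRecord:
    line_id: str
    gene: str  # collapsed gene name
    count: int
    length_bp: int  # spliced gene length
    fpkm: float
    repeat_proximal: bool | None = None


def _merged_models(annotations: list[GeneAnnotation]) -> dict[str, list[GeneAnnotation]]:
    """Group annotation records by gene name (collapses IR-duplicated pairs)."""
    merged: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        merged.setdefault(g.name, []).append(g)
    return merged


def count_reads_per_gene(alignments: list[Alignment],
                         annotations: list[GeneAnnotation],
                         genome_length: int,
                         min_overlap_frac: float = 0.5,
                         ) -> tuple[dict[str, int], int]:
    """Assign uniquely placed reads to collapsed genes by exon-union overlap.

    A read is assigned when >= ``min_overlap_frac`` of its aligned bases fall
    in one gene's exon union; if two genes overlap the read, the larger
    overlap wins and exact ties are left unassigned. Returns (per-gene
    counts, total assigned reads).
    """
    merged = _merged_models(annotations)
    pos_to_gene: dict[int, set[str]] = {}
    for name, models in merged.items():
        for g in models:
            for e in g.exons:
                for p in range(e.start, e.end):
                    pos_to_gene.setdefault(p % genome_length, set()).add(name)
    counts = {name: 0 for name in merged}
    total = 0

    def assign(pos: int, n: int) -> str | None:
        overlap: dict[str, int] = {}
        for off in range(n):
            for name in pos_to_gene.get((pos + off) % genome_length, ()):
                overlap[name] = overlap.get(name, 0) + 1
        if not overlap:
            return None
        best = max(overlap.values())
        if best < min_overlap_frac * n:
            return None
        winners = [n_ for n_, v in overlap.items() if v == best]
        return winners[0] if len(winners) == 1 else None  # tie -> unassigned

    for a in alignments:
        if a.status == "unaligned":
            continue
        if a.status == "unique":
            name = assign(a.pos, len(a.seq))
        else:
            # multi-placed: countable only when every placement lands in the
            # same collapsed gene (reads inside IR-duplicated genes)
            names = {assign(p, len(a.seq)) for p, _ in (a.placements or ())}
            name = names.pop() if len(names) == 1 else None
        if name is None:
            continue
        counts[name] += 1
        total += 1
    return counts, total


def fpkm(count: int, gene_length_bp: int, total_assigned_reads: int) -> float:
    """Reads per kilobase of gene per million assigned reads:
    ``count x 1e9 / (length x total)``."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if total_assigned_reads <= 0:
        raise ValueError("total assigned reads must be positive")
    return count * 1e9 / (gene_length_bp * total_assigned_reads)


def expression_table(alignments: list[Alignment],
                     annotations: list[GeneAnnotation], genome_length: int,
                     line_id: str = "",
                     repeat_proximal: dict[str, bool] | None = None,
                     ) -> pd.DataFrame:
    """Counts and FPKM per collapsed gene for one line."""
    counts, total = count_reads_per_gene(alignments, annotations, genome_length)
    merged = _merged_models(annotations)
    rows = []
    for name in sorted(merged):
        length = max(g.spliced_length for g in merged[name])
        rows.append({
            "line": line_id, "gene": name, "count": counts[name],
            "length_bp": length,
            "fpkm": fpkm(counts[name], length, total) if total else float("nan"),
            "repeat_proximal": (repeat_proximal or {}).get(name)})
    return pd.DataFrame(rows)


def relative_expression(bil: pd.DataFrame, maternal: pd.DataFrame,
                        down_threshold: float = 0.5,
                        up_threshold: float = 1.5,
                        ) -> tuple[pd.DataFrame, dict]:
    """Per-gene FPKM ratio (derived line / maternal) with change flags.

    Ratios strictly below ``down_threshold`` flag a gene down (>50% loss at
    the default), strictly above ``up_threshold`` up (>50% gain); a zero
    maternal FPKM makes the ratio not computable (NaN). Returns the joined
    table and a summary with flagged gene lists and the min/max ratio.
    """
    j = bil.merge(maternal, on="gene", suffixes=("_bil", "_mat"),
                  how="outer", indicator=True)
    mismatched = j[j["_merge"] != "both"]["gene"].tolist()
    j = j[j["_merge"] == "both"].drop(columns="_merge").copy()
    j["ratio"] = j["fpkm_bil"] / j["fpkm_mat"]
    j.loc[j["fpkm_mat"] == 0, "ratio"] = float("nan")
    j["down"] = j["ratio"] < down_threshold
    j["up"] = j["ratio"] > up_threshold
    valid = j[j["ratio"].notna()]
    summary = {
        "down_genes": sorted(valid[valid["down"]]["gene"]),
        "up_genes": sorted(valid[valid["up"]]["gene"]),
        "min_ratio": float(valid["ratio"].min()) if len(valid) else None,
        "max_ratio": float(valid["ratio"].max()) if len(valid) else None,
        "unshared_genes": sorted(mismatched),
    }
    return j, summary
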