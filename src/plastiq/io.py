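"""File I/O: FASTA/FASTQ records and GFF3 gene annotations.

GFF3 is 1-based closed on disk and converted to the package's 0-based
half-open circular intervals in memory. Origin-spanning features are not
written (plastome annotations are conventionally rotated away from the
origin first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, Interval
from .structure import GeneAnnotation

_BIOTYPE_TO_FTYPE = {"protein_coding": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}
_FTYPE_TO_BIOTYPE = {v: k for k, v in _BIOTYPE_TO_FTYPE.items()}


@dataclass
class SeqRead:
    """A sequencing read (FASTQ record; qualities optional)."""

    name: str
    seq: str
    qual: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    def tag(self, key: str) -> str | None:
        """Value of a ``key=value`` field in the read name (simulator truth)."""
        for part in self.name.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1:]
        return None


def read_fasta_genome(path: str | Path) -> CircularGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, "
                         f"found {len(records)}")
    rec = records[0]
    return CircularGenome(rec.id, str(rec.seq))


def write_fasta(genome: CircularGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="circular")
    SeqIO.write([rec], str(path), "fasta")


def write_fastq(reads: list[SeqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.name}\n{r.seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[SeqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations.get("phred_quality")
        qual = "".join(chr(q + 33) for q in quals) if quals else None
        out.append(SeqRead(rec.description or rec.id, str(rec.seq), qual))
    return out


def read_fasta_reads(path: str | Path) -> list[SeqRead]:
    return [SeqRead(rec.description or rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(annotations: list[GeneAnnotation], genome: CircularGenome,
               path: str | Path) -> None:
    L = len(genome)
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {L}"]
    for g in sorted(annotations, key=lambda g: g.extent().start):
        ext = g.extent()
        if ext.end > L:
            raise ValueError(f"{g.gene_id}: origin-spanning genes are not "
                             "written; rotate the genome first")
        biotype = _FTYPE_TO_BIOTYPE[g.ftype]
        lines.append("\t".join([
            genome.id, "plastiq", "gene", str(ext.start + 1), str(ext.end),
            ".", g.strand, ".",
            f"ID={g.gene_id};Name={g.name};gene_biotype={biotype}"]))
        child_type = "CDS" if g.ftype == "protein" else "exon"
        for k, e in enumerate(g.exons, 1):
            frame = "0" if child_type == "CDS" else "."
            lines.append("\t".join([
                genome.id, "plastiq", child_type, str(e.start + 1), str(e.end),
                ".", g.strand, frame,
                f"ID={g.gene_id}.{child_type.lower()}{k};Parent={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out: list[GeneAnnotation] = []
    for gene in db.features_of_type("gene"):
        exons = [Interval(c.start - 1, c.end)
                 for c in db.children(gene, featuretype=("CDS", "exon"))]
        if not exons:
            exons = [Interval(gene.start - 1, gene.end)]
        attrs = dict(gene.attributes)
        biotype = attrs.get("gene_biotype", ["protein_coding"])[0]
        out.append(GeneAnnotation(
            gene_id=gene.id,
            name=attrs.get("Name", [gene.id])[0],
            ftype=_BIOTYPE_TO_FTYPE.get(biotype, "protein"),
            strand=gene.strand,
            exons=tuple(exons),
            genome_id=gene.seqid))
    return out
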