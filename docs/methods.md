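# Methods

`plastiq` analyses circular plastid genomes (plastomes) for four kinds of
variation that escape a plain assembly comparison: quadripartite structure,
repeat-mediated recombination seen in long reads, RNA editing seen in RNA-seq,
and per-gene expression. Everything is exercisable on synthetic data with a
known ground truth; this note records the models, the defaults and why, the
numerical choices, and what the synthetic results do and do not show.

## Coordinates

All internal coordinates are 0-based, half-open, on a circle: an interval may
run past the sequence end (`end <= start + L`) to denote an origin-spanning
feature, and all arithmetic is modular. GFF3 I/O converts to and from 1-based
closed coordinates. Reported genomes are canonically rotated so the large
single-copy region starts at position 0 and is followed by IRa.

## Quadripartite structure

An angiosperm plastome is LSC + IRa + SSC + IRb with IRb the reverse
complement of IRa. `detect_quadripartite` finds the longest pair of disjoint
inverted repeats of at least `min_ir_len` (default 1000 bp — an order of
magnitude below real plastome IRs, far above background matches) by
seed-and-extend self-comparison: exact 32-mer anchors between the sequence
and its reverse complement, merged along anti-diagonals into maximal runs.
The larger remaining arc is the LSC. Absence of a qualifying pair and a tie
between two distinct maximal pairs are distinct errors (`StructureAbsentError`,
`AmbiguousStructureError`). Detection is invariant under rotation and strand
reversal of the input circle.

By default matching is exact (`max_mismatch_frac = 0`). Real IR copies are
near-identical (copy-correction keeps them so), and exactness makes
"maximal match" well-defined; a tolerant mode extends greedily across a
mismatch whenever the running identity stays at or above `1 - max_mismatch_frac`
and trims back to matching ends. The tolerant extension is greedy, not
optimal, and is offered as a flag rather than a default.

GC content is (G+C)/(A+C+G+T) with N excluded on both sides. The "gene
region" is the base-wise union of gene extents — introns included, both
strands, IR-duplicated genes at both loci — so gene + non-gene always equals
genome size; this is the only reading under which the two columns of a
per-line structure table partition the genome. Gene-order comparison is a
deliberate desk-scale stand-in for whole-genome alignment: after pivoting the
two circular gene orders to a common start, genes at differing ranks or with
differing strands are reported. On a circle a swapped pair is only
identifiable up to rotation, so the guarantee is "exactly the displaced genes
are flagged", not which member of an equivalent pair.

## Dispersed repeats and configurations

Repeat scanning runs on the genome with one IR copy excised (LSC + IRa +
SSC), since the IR would otherwise dominate a census of dispersed repeats.
`find_repeat_matches` reports every maximal ungapped repeated pair longer
than 20 bp (default `min_len = 21`), both orientations, seeded by exact
20-mers. With the default `min_identity = 1.0` the output is exactly the set
of maximal exact duplications, and the test suite holds it equal to an
independent brute-force per-diagonal scan on small genomes. Pairs whose
copies overlap or abut are set aside as tandem; palindromic self-pairs
(hairpins) are not dispersed repeats and are dropped. Copies are grouped by
overlap into families; families with exactly two copies become `RepeatType`s
(ids `D1, D2, …` / `I1, …` in genome order), the unit of configuration
analysis — recombination between two copies yields exactly two products, so
only two-copy repeats have a clean four-configuration logic.

A two-copy repeat R with upstream/downstream flanks a,b (copy 1) and c,d
(copy 2) defines four junctions: parental `a-R-b`, `c-R-d` and recombinant
`a-R-d`, `c-R-b`. For inverted repeats the copy-2 flanks are taken in copy 1's
unit frame, i.e. reverse-complemented genomic context; the recombinant
junctions then correspond to an inversion of the inter-copy segment. Flanks
default to 200 bp; a flank that would run into another repeat copy is shrunk
with a warning, and below 50 bp (the anchor minimum) enumeration fails —
without that much unique flank no read can be anchored unambiguously.
Repeat–gene proximity uses a circular gap of at most 2000 bp between any
repeat copy and the gene extent.

## Recombination from reads

One long read is one observation. A read supports a configuration when the
configuration's *diagnostic core* — `min_anchor` flank bases + unit +
`min_anchor` flank bases — occurs in the read (either orientation) within an
edit distance of `max_mismatch_frac` times the core length, as an occurrence
of the full core length (end-gaps are not allowed to shave the anchors; this
keeps the anchor threshold sharp on clean data). If more than one
configuration matches, the strict best edit distance wins; any tie, or no
hit, is ambiguous. Defaults `min_anchor = 50` and `max_mismatch_frac = 0.1`
accept long-read error rates while keeping the recombinant/parental anchors
(which differ in ~74% of positions on random flanks) far outside the edit
budget; both are exposed as flags.

Configuration content is the count of one configuration over the total of
the four, per repeat (undefined and flagged when the total is zero; ambiguous
reads are in no denominator). The recombination rate is the recombinant
share, and relative content is a derived line's content over the maternal
content, as a percentage; zero maternal content makes the value
not-computable, never infinite. Pooled-across-repeats denominators are
provided as a secondary view (`pooled_counts`).

## RNA editing

`NaiveMapper` places substitution-only reads on the circular genome with
exact 31-mer seeds at several offsets (with a sliding-seed fallback for
densely mismatched reads), scores candidates by full-length mismatch count,
and flags ties between distinct loci as multi-placed — reads from inside the
IR are the canonical case. Pileups cover annotated protein-coding CDS only,
re-oriented to each gene's sense strand (minus-strand genes complement the
genomic bases and reverse the position order; spliced positions concatenate
across introns). Multi-placed reads are excluded from pileups.

A site is called when the sense-strand reference is C with T in reads (C-to-U)
or T with C (U-to-C), at depth >= 50, rate >= `min_rate` and >= `min_edited_reads`
supporting reads. The depth cutoff is the analysis's coverage floor; the
other two defaults (0.05 and 3) suppress sequencing-error artifacts at that
depth (at 0.1% error, a false site needs >= 3 same-direction errors and a 5%
rate) and are flags. All other mismatch classes are counted separately as a
noise diagnostic, not as editing. Codon effects use NCBI translation table 11
(bacterial/plastid); positions are keyed `gene-CDSposition`.

Cross-line comparison takes the union of called sites; in a line where a
site was not called, its rate is read off the pileup when coverage allows
(a covered, unedited site has rate 0), and is not comparable below the depth
floor. A site is editing-rate-changed when its rate differs from the
reference (maternal) line by **more than 10 absolute percentage points**.
The absolute reading is deliberate: with rates 17.2% (reference), 6.3% and
25.3%, only the 6.3% line is a change (10.9 pp vs 8.1 pp) — a relative
reading would flag both, contradicting how such sites are narrated. The
threshold is a flag.

## Expression

Plastid genes are single-isoform, so no transcript-abundance EM is needed: a
uniquely placed read belongs to the gene covering the largest share of its
aligned bases if that share is at least half, larger overlap winning and
exact ties unassigned. Genes duplicated between the IR copies are collapsed
under one gene name before counting; a multi-placed read is counted when all
its best placements fall inside the same collapsed gene (otherwise IR genes
would read as silent), which applies to internally mapped reads — SAM input
carries no alternative placements. FPKM = count x 10^9 / (length x total
assigned). Relative expression is FPKM over maternal FPKM; ratios strictly
below 0.5 / above 1.5 flag a gene down / up by more than 50%, and
repeat-proximity flags are joined from the repeat scan.

## Synthetic data and ground truth

The generator's default dimensions are the studied maternal rice plastome:
134,561 bp (LSC 80,572 / SSC 12,381 / IR 20,804), 39% GC, 110 genes in the
76 protein / 30 tRNA / 4 rRNA ratio with 18 IR-duplicated gene names, and 8
two-copy dispersed repeats with units in the 25–60 bp range (the real census:
16 copies, ~0.5% of the IR-reduced genome, nothing above 1 kb). Genes are
annotated intervals over the random background (single-exon; intron handling
is tested with hand-built two-exon fixtures); repeat units are written into
gene-free gaps. Read defaults: single-end DNA long reads 1–3 kb at 20x,
single-end RNA reads of 150 bp at 100x, substitution-only errors at 0.1%.

Constraints the generator enforces so estimators can be scored exactly:

- planted repeats lie outside the IRs, outside genes, pairwise more than one
  flank length apart, and the two copies of one repeat more than one maximal
  DNA read length apart (a read spanning both junctions of a repeat supports
  two configurations at once and would be ambiguous by construction);
- single-base chance extensions at IR and repeat-copy boundaries are broken,
  so maximal matches end exactly at planted coordinates;
- flank pairs are checked for < 60% identity (configurations must be
  decidable on error-free data);
- editing sites are forced to the required sense-strand base (C or T) inside
  single-copy protein genes.

DNA reads are drawn from a molecule population: a parental pool plus one
pool per repeat with recombinant fraction f_r (mutually exclusive, so each
molecule carries at most one crossover and the fractions must sum below 1).
A direct-repeat crossover resolves the circle into two smaller circles; an
inverted-repeat crossover inverts the inter-copy segment in place. Copies of
other repeats keep parental context in every product, so the per-junction
recombinant read fraction is exactly f_r — the binomial oracle for the
recovery tests. Read names carry the source pool, coordinates, strand and
every junction the read fully spans with its flank coverages.

RNA reads are sampled from spliced sense transcripts with probability
proportional to expression level x transcript length (equal-length genes
therefore yield count ratios equal to their level ratios); each covering
read carries each planted edit independently with probability equal to the
site's rate; errors follow. IR-duplicated names are transcribed once.

What the synthetic data does **not** emulate: indels and realistic long-read
error profiles (the bundled mapper and classifier are substitution-only by
design), transcript degradation/coverage bias, strand-specific library
artifacts, partial editing linkage between nearby sites on one molecule
(edits are independent per read), substoichiometric recombinant topologies
beyond single crossovers, and IR boundary shifts. Passing tests show the
estimators recover planted parameters under this model at binomial
precision; they do not validate mapper behaviour on indel-rich reads or
editing calls in genes with extreme site density (clusters of high-rate
sites closer than a seed length can still defeat exact seeding — the study's
observed density, ~2 sites per gene, is far below that).

## Problem sizes and determinism

Tests and the acceptance script use reduced genomes (≈ 5–11 kb) for
read-based recovery — chosen so every binomial recovery check has >= 2,000
junction reads or >= 200–1,100x site depth — and the full 134.5 kb scale for
sequence-level statistics (structure, census), where no reads are needed.
All randomness flows from explicit integer seeds through numpy Generators;
identical seed and configuration reproduce byte-identical genomes, reads,
manifests and pipeline TSVs (verified by checksum in the pipeline and the
acceptance script).
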