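"""Read classification over repeat junctions and recombination quantification.

A long read is informative for a two-copy repeat when it spans the whole
repeat unit with an anchor of at least ``min_anchor`` bases in *both* flanks.
Such a read supports exactly one of the four configurations (parental ab/cd,
recombinant ad/cb); everything else is ambiguous. The content of a
configuration is its read count divided by all configuration-supporting reads
of that repeat, the recombination rate is the recombinant fraction, and the
relative content of a configuration in a derived line is its content divided
by the content in the maternal line, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .genome import revcomp
from .io import SeqRead
from .repeatscan import RepeatConfiguration

LABELS = ("ab", "cd", "ad", "cb")


@dataclass
class ConfigurationCounts:
    """Per-line, per-repeat read counts over the four configurations."""

    line_id: str
    repeat_id: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(LABELS, 0))
    ambiguous: int = 0

    def __post_init__(self) -> None:
        if set(self.counts) != set(LABELS):
            raise ValueError(f"counts must cover exactly {LABELS}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative configuration counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def contents(self) -> dict[str, float] | None:
        """Per-configuration content; None when no read was counted."""
        return configuration_content(self.counts)

    @property
    def recombination_rate(self) -> float | None:
        if self.total == 0:
            return None
        return (self.counts["ad"] + self.counts["cb"]) / self.total


@dataclass(frozen=True)
class RelativeContent:
    line_id: str
    repeat_id: str
    label: str
    relative_pct: float | None  # None when the maternal content is zero


class JunctionClassifier:
    """Anchored classification of reads against one repeat's four junctions.

    The diagnostic core of a configuration is its junction trimmed to
    ``min_anchor`` flank bases on either side of the unit; a read supports a
    configuration when the core occurs in the read (either orientation)
    within an edit distance of ``max_mismatch_frac`` x core length. The
    winning label must be a strict best — any tie, or no hit, is ambiguous.
    """

    def __init__(self, configurations: dict[str, RepeatConfiguration],
                 min_anchor: int = 50, max_mismatch_frac: float = 0.1):
        if set(configurations) != set(LABELS):
            raise ValueError(f"need exactly the four configurations {LABELS}")
        junctions = {lab: c.junction for lab, c in configurations.items()}
        if len(set(junctions.values())) != 4:
            raise ValueError("duplicate junction sequences")
        cfg = configurations["ab"]
        if min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")
        if min_anchor > cfg.flank_len:
            raise ValueError(
                f"min_anchor {min_anchor} exceeds flank length {cfg.flank_len}")
        self.repeat_id = cfg.repeat_id
        self.min_anchor = min_anchor
        self.cores = {
            lab: c.junction[c.flank_len - min_anchor:
                            c.flank_len + c.unit_len + min_anchor]
            for lab, c in configurations.items()}
        self.max_edits = {lab: int(max_mismatch_frac * len(core))
                          for lab, core in self.cores.items()}

    def classify(self, read: str | SeqRead) -> str:
        seq = read.seq if isinstance(read, SeqRead) else read
        rc = revcomp(seq)
        best: dict[str, int] = {}
        for lab, core in self.cores.items():
            if len(seq) < len(core):
                continue
            dists = []
            for target in (seq, rc):
                res = edlib.align(core, target, mode="HW", task="locations",
                                  k=self.max_edits[lab])
                if res["editDistance"] == -1:
                    continue
                # demand a full-length (ungapped) occurrence: edlib's infix
                # mode would otherwise let an end-deletion shave the anchor
                # below min_anchor for the cost of one edit
                if any(e - s + 1 == len(core)
                       for s, e in res["locations"] if s is not None):
                    dists.append(res["editDistance"])
            if dists:
                best[lab] = min(dists)
        if not best:
            return "ambiguous"
        dmin = min(best.values())
        winners = [lab for lab, d in best.items() if d == dmin]
        return winners[0] if len(winners) == 1 else "ambiguous"


def classify_read(read: str | SeqRead,
                  configurations: dict[str, RepeatConfiguration],
                  min_anchor: int = 50,
                  max_mismatch_frac: float = 0.1) -> str:
    """Label a read as ab, cd, ad, cb or 'ambiguous' (see
    :class:`JunctionClassifier`)."""
    return JunctionClassifier(configurations, min_anchor,
                              max_mismatch_frac).classify(read)


def count_configurations(reads, configurations: dict[str, RepeatConfiguration],
                         line_id: str = "", min_anchor: int = 50,
                         max_mismatch_frac: float = 0.1) -> ConfigurationCounts:
    """Classify a read set against one repeat's configurations."""
    clf = JunctionClassifier(configurations, min_anchor, max_mismatch_frac)
    cc = ConfigurationCounts(line_id=line_id, repeat_id=clf.repeat_id)
    for read in reads:
        lab = clf.classify(read)
        if lab == "ambiguous":
            cc.ambiguous += 1
        else:
            cc.counts[lab] += 1
    return cc


def configuration_content(counts: dict[str, int]) -> dict[str, float] | None:
    """Each configuration's read count over the four-configuration total.

    Returns None (undefined) when no configuration read was observed.
    """
    if any(counts.get(lab, 0) < 0 for lab in LABELS):
        raise ValueError("negative configuration counts")
    total = sum(counts.get(lab, 0) for lab in LABELS)
    if total == 0:
        return None
    return {lab: counts.get(lab, 0) / total for lab in LABELS}


def relative_content(bil: ConfigurationCounts,
                     maternal: ConfigurationCounts) -> list[RelativeContent]:
    """Content in a derived line over content in the maternal line, x100.

    Configurations with zero maternal content are reported as not computable
    (None), never as infinity.
    """
    if bil.repeat_id != maternal.repeat_id:
        raise ValueError(f"repeat mismatch: {bil.repeat_id} vs {maternal.repeat_id}")
    c_bil = bil.contents
    c_mat = maternal.contents
    out = []
    for lab in LABELS:
        if c_bil is None or c_mat is None or c_mat[lab] == 0:
            pct = None
        else:
            pct = 100.0 * c_bil[lab] / c_mat[lab]
        out.append(RelativeContent(bil.line_id, bil.repeat_id, lab, pct))
    return out


def recombination_rate_table(
        per_line: dict[str, dict[str, ConfigurationCounts]]) -> pd.DataFrame:
    """Recombination-rate matrix (lines x repeats), ready for plotting."""
    lines = sorted(per_line)
    repeats = sorted({rid for d in per_line.values() for rid in d})
    data = {rid: [
        (per_line[ln][rid].recombination_rate if rid in per_line[ln] else None)
        for ln in lines] for rid in repeats}
    return pd.DataFrame(data, index=pd.Index(lines, name="line"))


def pooled_counts(per_repeat: dict[str, ConfigurationCounts],
                  line_id: str = "") -> ConfigurationCounts:
    """Counts pooled across repeats (the alternative reading of 'all mapping
    reads of repeat configurations'); reported alongside the per-repeat
    primary quantities."""
    cc = ConfigurationCounts(line_id=line_id, repeat_id="pooled")
    for c in per_repeat.values():
        for lab in LABELS:
            cc.counts[lab] += c.counts[lab]
        cc.ambiguous += c.ambiguous
    return cc
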