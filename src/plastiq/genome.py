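"""Circular nucleotide sequences and modular interval arithmetic.

Plastomes are circular molecules, so every coordinate in this package is
0-based and half-open *on the circle*: an interval may run past the sequence
end (``end`` up to ``start + L``) to denote an origin-spanning feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval on a circle; ``end`` may exceed the circle length.

    Invariant (enforced by :func:`normalize`): ``0 <= start < L`` and
    ``start < end <= start + L``.
    """

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize(iv: Interval, L: int) -> Interval:
    """Re-express an interval with ``start`` in ``[0, L)``."""
    if not 0 < len(iv) <= L:
        raise ValueError(f"interval length must be in (0, {L}]: {iv}")
    s = iv.start % L
    return Interval(s, s + len(iv))


def _linear_parts(iv: Interval, L: int) -> list[tuple[int, int]]:
    iv = normalize(iv, L)
    if iv.end <= L:
        return [(iv.start, iv.end)]
    return [(iv.start, L), (0, iv.end - L)]


def intervals_overlap(a: Interval, b: Interval, L: int) -> bool:
    """Do two circular intervals share at least one position?"""
    for s1, e1 in _linear_parts(a, L):
        for s2, e2 in _linear_parts(b, L):
            if s1 < e2 and s2 < e1:
                return True
    return False


def circular_gap(a: Interval, b: Interval, L: int) -> int:
    """Number of bases strictly between two circular intervals (0 if they touch
    or overlap), taking the shorter way around."""
    if intervals_overlap(a, b, L):
        return 0
    a, b = normalize(a, L), normalize(b, L)
    g1 = (b.start - a.end) % L
    g2 = (a.start - b.end) % L
    return min(g1, g2)


def interval_union_size(intervals: list[Interval], L: int) -> int:
    """Size of the base-wise union of circular intervals."""
    parts: list[tuple[int, int]] = []
    for iv in intervals:
        parts.extend(_linear_parts(iv, L))
    parts.sort()
    total = 0
    cur_s = cur_e = None
    for s, e in parts:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


@dataclass
class CircularGenome:
    """A circular nucleotide sequence with an identifier."""

    id: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("empty genome sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in genome {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Circular substring; ``end - start`` must be in ``(0, L]``."""
        L = len(self.seq)
        n = end - start
        if not 0 < n <= L:
            raise ValueError(f"fetch length {n} outside (0, {L}]")
        s = start % L
        e = s + n
        if e <= L:
            return self.seq[s:e]
        return self.seq[s:] + self.seq[: e - L]

    def fetch_interval(self, iv: Interval) -> str:
        return self.fetch(iv.start, iv.end)

    def rotate(self, offset: int) -> "CircularGenome":
        """New genome starting at ``offset`` of this one (same circle)."""
        L = len(self.seq)
        o = offset % L
        return CircularGenome(self.id, self.seq[o:] + self.seq[:o])

    def reverse_complement(self) -> "CircularGenome":
        return CircularGenome(self.id, revcomp(self.seq))
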