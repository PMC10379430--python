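"""Seed-and-extend discovery of maximal ungapped self-matches on a circle.

Used by quadripartite-structure detection (inverted matches >= ~20 kb) and by
dispersed-repeat scanning (matches > 20 bp in both orientations). Seeds are
exact ``word_size``-mers; extension is ungapped. With ``max_mismatch_frac = 0``
(the default everywhere) the output is exactly the set of maximal exact
repeated pairs, which is what the brute-force oracles in the test-suite
enumerate. With a nonzero tolerance, extension greedily crosses a mismatch
whenever the running identity stays at or above ``1 - max_mismatch_frac``, and
the final match is trimmed back to matching bases at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Interval, complement, revcomp


@dataclass(frozen=True)
class MatchPair:
    """A maximal ungapped match between two loci of one circular sequence."""

    copy1: Interval
    copy2: Interval
    orientation: str  # 'direct' | 'inverted'
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length


def _extend_run(matches_at, anchor_lo: int, anchor_hi: int, L: int,
                max_mismatch_frac: float) -> tuple[int, int, int]:
    """Maximal run of the predicate ``matches_at(p)`` around ``[anchor_lo,
    anchor_hi)``; returns (start, end, n_mismatch). Positions are taken mod L
    and the run length is capped at L (a fully periodic circle)."""
    lo, hi = anchor_lo, anchor_hi
    mm = 0
    # exact growth first
    while hi - lo < L and matches_at(hi):
        hi += 1
    while hi - lo < L and matches_at(lo - 1):
        lo -= 1
    if max_mismatch_frac > 0:
        grown = True
        while grown and hi - lo < L:
            grown = False
            # try to cross a mismatch on the right, then the left
            for side in ("right", "left"):
                if hi - lo >= L:
                    break
                probe = hi if side == "right" else lo - 1
                if matches_at(probe):  # already consumed by exact growth
                    continue
                if (mm + 1) / (hi - lo + 1) <= max_mismatch_frac:
                    # only worthwhile if a matching base lies just beyond
                    nxt = probe + 1 if side == "right" else probe - 1
                    if abs(nxt - (lo if side == "left" else hi)) < L and matches_at(nxt):
                        mm += 1
                        if side == "right":
                            hi = probe + 1
                        else:
                            lo = probe
                        # exact growth resumes
                        while hi - lo < L and matches_at(hi):
                            hi += 1
                        while hi - lo < L and matches_at(lo - 1):
                            lo -= 1
                        grown = True
    return lo, hi, mm


def _circular_kmers(S: str, k: int) -> dict[str, list[int]]:
    L = len(S)
    S2 = S + S[: k - 1]
    buckets: dict[str, list[int]] = {}
    for i in range(L):
        buckets.setdefault(S2[i : i + k], []).append(i)
    return buckets


def direct_maximal_matches(S: str, word_size: int, min_len: int,
                           max_mismatch_frac: float = 0.0) -> list[MatchPair]:
    """Maximal direct (same-strand) repeated pairs of a circular sequence."""
    L = len(S)
    if L < word_size:
        raise ValueError(f"sequence length {L} < word size {word_size}")
    buckets = _circular_kmers(S, word_size)
    done: set[tuple[int, int]] = set()  # (diagonal, run start mod L)
    out: dict[tuple, MatchPair] = {}
    for poss in buckets.values():
        if len(poss) < 2:
            continue
        for i in poss:
            for j in poss:
                if i == j:
                    continue
                d = (j - i) % L
                if d == 0:
                    continue

                def m_at(p, d=d):
                    return S[p % L] == S[(p + d) % L]

                lo, hi, mm = _extend_run(m_at, i, i + word_size, L, max_mismatch_frac)
                key_run = (d, lo % L)
                if key_run in done:
                    continue
                done.add(key_run)
                length = hi - lo
                if length < min_len:
                    continue
                c1 = Interval(lo % L, lo % L + length)
                c2 = Interval((lo + d) % L, (lo + d) % L + length)
                starts = sorted([c1.start, c2.start])
                key = ("D", starts[0], starts[1], length)
                if key not in out:
                    a, b = (c1, c2) if c1.start <= c2.start else (c2, c1)
                    out[key] = MatchPair(a, b, "direct", length, mm)
    return sorted(out.values(), key=lambda m: (m.copy1.start, m.copy2.start))


def inverted_maximal_matches(S: str, word_size: int, min_len: int,
                             max_mismatch_frac: float = 0.0) -> list[MatchPair]:
    """Maximal inverted (reverse-complement) repeated pairs of a circular
    sequence. Self-symmetric (palindromic hairpin) runs, where the two copies
    coincide, are not reported as dispersed pairs."""
    L = len(S)
    if L < word_size:
        raise ValueError(f"sequence length {L} < word size {word_size}")
    buckets = _circular_kmers(S, word_size)
    comp = complement(S)
    S2 = S + S[: word_size - 1]
    done: set[tuple[int, int]] = set()  # (anti-diagonal, run start mod L)
    out: dict[tuple, MatchPair] = {}
    for j in range(L):
        w = revcomp(S2[j : j + word_size])
        for i in buckets.get(w, ()):
            if i > j:
                continue
            c = (i + j + word_size - 1) % L

            def m_at(p, c=c):
                return S[p % L] == comp[(c - p) % L]

            lo, hi, mm = _extend_run(m_at, i, i + word_size, L, max_mismatch_frac)
            key_run = (c, lo % L)
            if key_run in done:
                continue
            done.add(key_run)
            length = hi - lo
            if length < min_len:
                continue
            s1 = lo % L
            s2 = (c - hi + 1) % L
            if s1 == s2:
                continue  # palindromic self-pair
            c1 = Interval(s1, s1 + length)
            c2 = Interval(s2, s2 + length)
            starts = sorted([s1, s2])
            key = ("I", starts[0], starts[1], length)
            if key not in out:
                a, b = (c1, c2) if c1.start <= c2.start else (c2, c1)
                out[key] = MatchPair(a, b, "inverted", length, mm)
    return sorted(out.values(), key=lambda m: (m.copy1.start, m.copy2.start))
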