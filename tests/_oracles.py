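"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: maximal
repeated pairs are enumerated by scanning every diagonal (direct) and
anti-diagonal (inverted) of the circular self-comparison matrix with numpy.
"""

from __future__ import annotations

import numpy as np

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[a] = b


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal circular runs of True with length >= min_len: (start, len)."""
    L = len(mask)
    if mask.all():
        return [(0, L)]
    if not mask.any():
        return []
    m2 = np.concatenate([mask, mask]).astype(np.int8)
    d = np.diff(m2)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m2[0]:
        starts = np.concatenate([[0], starts])
    idx = np.searchsorted(ends, starts, side="right")
    keep = (starts < L) & (idx < len(ends))
    starts, idx = starts[keep], idx[keep]
    lens = ends[idx] - starts
    out = []
    for s, ln in zip(starts, lens):
        ln = min(int(ln), L)
        if ln >= min_len:
            out.append((int(s), ln))
    return out


def brute_force_repeat_pairs(seq: str, min_len: int = 21) -> set[tuple]:
    """Every maximal exact repeated pair of a circular sequence, both
    orientations, as canonical keys (orient, start_a, start_b, length);
    palindromic self-pairs excluded."""
    L = len(seq)
    A = np.frombuffer(seq.encode(), dtype=np.uint8)
    A2 = np.concatenate([A, A])
    B = _COMP_TABLE[A]
    Drev2 = np.concatenate([B[::-1], B[::-1]])
    out: set[tuple] = set()
    for d in range(1, L):
        m = A == A2[d: d + L]
        for u, ln in _runs(m, min_len):
            s1, s2 = u % L, (u + d) % L
            out.add(("D",) + tuple(sorted((s1, s2))) + (ln,))
    for c in range(L):
        s0 = (L - 1 - c) % L
        m = A == Drev2[s0: s0 + L]
        for u, ln in _runs(m, min_len):
            s1 = u % L
            s2 = (c - (u + ln) + 1) % L
            if s1 == s2:
                continue  # palindromic hairpin, not a dispersed pair
            out.add(("I",) + tuple(sorted((s1, s2))) + (ln,))
    return out


def match_keys(matches, L: int) -> set[tuple]:
    """Canonical keys for the package's MatchPair list (same key scheme)."""
    out = set()
    for m in matches:
        o = "D" if m.orientation == "direct" else "I"
        out.add((o,) + tuple(sorted((m.copy1.start % L, m.copy2.start % L)))
                + (m.length,))
    return out


# Frozen NCBI translation table 11 (bacterial/plastid); independent of any
# library the implementation uses.
CODON_TABLE_11 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
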