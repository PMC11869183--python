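"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by the most direct method available
(explicit enumeration, textbook dynamic programming, closed forms) without
touching the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# k-mers


def brute_force_canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k].upper()
        if any(c not in "ACGT" for c in w):
            continue
        rc = str(Seq(w).reverse_complement())
        out.add(min(w, rc))
    return out


def mash_closed_form(j: float, k: int) -> float:
    if j == 0:
        return 1.0
    return min(1.0, max(0.0, -(1.0 / k) * math.log(2.0 * j / (1.0 + j))))


# ---------------------------------------------------------------------------
# affine-gap global alignment (Gotoh), textbook recurrences


def gotoh_global_score(a: str, b: str, matrix_name: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    m = substitution_matrices.load(matrix_name)
    n1, n2 = len(a), len(b)
    NEG = -1e18
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n1 + 1, n2 + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, n2 + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            s = m[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend, X[i, j - 1] - gap_open)
    return float(max(M[n1, n2], X[n1, n2], Y[n1, n2]))


def similarity_oracle(a: str, b: str) -> float:
    m = substitution_matrices.load("BLOSUM62")
    saa = sum(m[c, c] for c in a)
    sbb = sum(m[c, c] for c in b)
    s = gotoh_global_score(a, b)
    return float(np.clip(100.0 * 2.0 * s / (saa + sbb), 0.0, 100.0))


# ---------------------------------------------------------------------------
# NG86 brute force

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_oracle(seq1: str, seq2: str) -> tuple[float, float, bool]:
    """(dn, ds, valid) by direct enumeration of sites and pathways."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        for codon in (seq1[i : i + 3], seq2[i : i + 3]):
            syn = 0.0
            for pos, alt in itertools.product(range(3), "ACGT"):
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut not in _STOPS and _aa(mut) == _aa(codon):
                    syn += 1.0
            S += syn / 3.0 / 2.0
            N += (3.0 - syn / 3.0) / 2.0
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        positions = [p for p in range(3) if c1[p] != c2[p]]
        if not positions:
            continue
        paths = []
        for order in itertools.permutations(positions):
            cur, syn, non, blocked = c1, 0.0, 0.0, False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if nxt in _STOPS:
                    blocked = True
                if _aa(cur) == _aa(nxt):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            paths.append((syn, non, blocked))
        open_paths = [p for p in paths if not p[2]] or paths
        Sd += sum(p[0] for p in open_paths) / len(open_paths)
        Nd += sum(p[1] for p in open_paths) / len(open_paths)
    ps, pn = Sd / S, Nd / N

    def jc(p):
        return None if p >= 0.75 else max(0.0, -0.75 * math.log(1 - 4 * p / 3))

    ds, dn = jc(ps), jc(pn)
    valid = ds is not None and dn is not None
    return (dn if valid else math.inf, ds if valid else math.inf, valid)


# ---------------------------------------------------------------------------
# trees


def tip_sets(tree) -> list[frozenset[str]]:
    """All clade tip sets of a rooted skbio tree, by fresh recursion."""
    out = []

    def rec(node) -> frozenset[str]:
        if node.is_tip():
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(rec(c) for c in node.children))
        out.append(s)
        return s

    rec(tree)
    return out


# ---------------------------------------------------------------------------
# retention / coverage


def window_retention_oracle(retained_flags: list[bool], window: int, step: int) -> list[float]:
    out = []
    start = 0
    while start + window <= len(retained_flags):
        out.append(100.0 * sum(retained_flags[start : start + window]) / window)
        start += step
    return out


def coverage_oracle(length: int, intervals: list[tuple[int, int]], window: int) -> list[float]:
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    out = []
    pos = 0
    while pos < length:
        wend = min(pos + window, length)
        out.append(100.0 * covered[pos:wend].sum() / (wend - pos))
        pos = wend
    return out
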