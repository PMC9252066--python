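"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by exhaustive enumeration or grid search,
deliberately avoiding the code paths (and, where possible, the data
structures) of the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# PROSITE matching by reachable-position dynamic programming
# ---------------------------------------------------------------------------

def prosite_matches_dp(elements, seq: str, n_anchor=False, c_anchor=False):
    """All (start, end) 1-based spans matching the element list, longest per start.

    *elements* are (kind, residues, min_rep, max_rep) tuples. A set of
    reachable string positions is propagated element by element — no
    backtracking, so the search strategy is independent of the scanner's.
    """

    def char_ok(kind, residues, ch):
        if ch == "X":
            return kind == "wildcard"
        if kind == "wildcard":
            return True
        if kind in ("fixed", "allowed"):
            return ch in residues
        return ch not in residues

    n = len(seq)
    out = []
    starts = [0] if n_anchor else range(n)
    for s in starts:
        reachable = {s}
        for kind, residues, mn, mx in elements:
            nxt = set()
            for p in reachable:
                run = 0
                while run < mx and p + run < n and char_ok(kind, residues, seq[p + run]):
                    run += 1
                for r in range(mn, run + 1):
                    nxt.add(p + r)
            reachable = nxt
            if not reachable:
                break
        ends = {e for e in reachable if not c_anchor or e == n}
        if ends:
            e = max(ends)
            out.append((s + 1, e))
    return out


# ---------------------------------------------------------------------------
# Global alignment by exhaustive enumeration (tiny sequences, linear gaps)
# ---------------------------------------------------------------------------

def brute_force_global_score(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0):
    """Optimal global alignment score by enumerating all alignments."""

    best = [-math.inf]

    def rec(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Nei–Gojobori counting, independent route via Biopython translation
# ---------------------------------------------------------------------------

_NT = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str):
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in _NT if b != codon[pos]]
        alts = [c for c in alts if _aa(c) != "*"]
        if alts:
            syn += sum(_aa(c) == _aa(codon) for c in alts) / len(alts)
    return syn, 3.0 - syn


def oracle_differences(ca: str, cb: str):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur, path = ca, []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
            path.append((cur, nxt))
            cur = nxt
        if not blocked:
            results.append(path)
    if not results:
        results = []
        for order in itertools.permutations(positions):
            cur, path = ca, []
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                path.append((cur, nxt))
                cur = nxt
            results.append(path)
    syn = np.mean([sum(_aa(x) == _aa(y) for x, y in path) for path in results])
    return float(syn), float(len(positions) - syn)


def oracle_kaks(cds_a: str, cds_b: str):
    """NG86 Ka/Ks recomputed from scratch over equal-length stop-free CDS."""
    ca = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    cb = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    S = N = Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        sx, nx = oracle_sites(x)
        sy, ny = oracle_sites(y)
        S += (sx + sy) / 2
        N += (nx + ny) / 2
        ds, dn = oracle_differences(x, y)
        Sd += ds
        Nd += dn

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log1p(-4 * p / 3)

    return jc(Nd / N), jc(Sd / S)


# ---------------------------------------------------------------------------
# Isoelectric point by grid search
# ---------------------------------------------------------------------------

def grid_pi(sequence: str, n_steps: int = 1_000_000):
    """pH grid point of minimal |net charge| using the Bjellqvist constants."""
    ph = np.linspace(0.0, 14.0, n_steps)
    charge = 10**7.5 / (10**7.5 + 10**ph) - 10**ph / (10**3.55 + 10**ph)
    for aa, pka in (("H", 5.98), ("K", 10.0), ("R", 12.0)):
        n = sequence.count(aa)
        if n:
            charge = charge + n * 10**pka / (10**pka + 10**ph)
    for aa, pka in (("D", 4.05), ("E", 4.45), ("C", 9.0), ("Y", 10.0)):
        n = sequence.count(aa)
        if n:
            charge = charge - n * 10**ph / (10**pka + 10**ph)
    return float(ph[np.argmin(np.abs(charge))])
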