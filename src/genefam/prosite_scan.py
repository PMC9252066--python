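"""PROSITE-syntax pattern parsing and protein scanning.

Implements the classical PROSITE pattern language — ``-``-separated elements,
``[..]`` allowed sets, ``{..}`` forbidden sets, ``x`` wildcards, ``(n)`` /
``(n,m)`` repetition, ``<`` / ``>`` terminal anchors — and a scanner that
reports, for every start position, the longest subsequence matching the whole
pattern. This is used to flag the aldehyde-dehydrogenase glutamic-acid
(PS00687) and cysteine (PS00070) active sites in candidate proteins.

Ambiguity handling is conservative: ``X`` in a protein matches only wildcard
elements; ``B``/``Z`` match only sets that list them explicitly. Repetition
ranges are explored with full backtracking, so ``x(n,m)`` admits every length
in ``[n, m]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

__all__ = [
    "PatternParseError",
    "PatternElement",
    "PrositePattern",
    "SiteMatch",
    "parse_pattern",
    "scan",
    "detect_active_sites",
    "load_pattern_catalog",
    "default_pattern_catalog",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class PatternParseError(ValueError):
    """Malformed PROSITE pattern text; carries the offending offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: fixed residue, allowed/forbidden set, or wildcard."""

    kind: Literal["fixed", "allowed", "forbidden", "wildcard"]
    residues: frozenset[str]
    min_rep: int = 1
    max_rep: int = 1

    def matches(self, aa: str) -> bool:
        if aa == "X":
            # unknown residue: only a wildcard can claim it
            return self.kind == "wildcard"
        if self.kind == "wildcard":
            return True
        if self.kind == "fixed" or self.kind == "allowed":
            return aa in self.residues
        return aa not in self.residues  # forbidden set


@dataclass(frozen=True)
class PrositePattern:
    accession: str
    elements: tuple[PatternElement, ...]
    n_anchor: bool = False
    c_anchor: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.min_rep for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_rep for e in self.elements)


@dataclass(frozen=True)
class SiteMatch:
    accession: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    matched_subsequence: str


_REP_RE = re.compile(r"\((\d+)(?:,(\d+))?\)")


def parse_pattern(text: str, accession: str = "") -> PrositePattern:
    """Parse PROSITE pattern syntax into a :class:`PrositePattern`."""
    raw = text.strip().rstrip(".")
    n_anchor = c_anchor = False
    pos = 0
    if raw.startswith("<"):
        n_anchor = True
        raw = raw[1:]
        pos += 1
    if raw.endswith(">"):
        c_anchor = True
        raw = raw[:-1]
    if not raw:
        raise PatternParseError("empty pattern", 0)

    elements: list[PatternElement] = []
    for tok in raw.split("-"):
        if not tok:
            raise PatternParseError("empty element", pos)
        body = tok
        min_rep = max_rep = 1
        m = _REP_RE.search(tok)
        if m:
            if m.end() != len(tok):
                raise PatternParseError(f"malformed repetition in {tok!r}", pos)
            min_rep = int(m.group(1))
            max_rep = int(m.group(2)) if m.group(2) else min_rep
            if min_rep > max_rep:
                raise PatternParseError(f"repetition min > max in {tok!r}", pos)
            body = tok[: m.start()]
        if body == "x":
            elements.append(PatternElement("wildcard", frozenset(), min_rep, max_rep))
        elif body.startswith("["):
            if not body.endswith("]") or len(body) < 3:
                raise PatternParseError(f"unbalanced or empty set in {tok!r}", pos)
            residues = frozenset(body[1:-1])
            if not residues <= AMINO_ACIDS | {"B", "Z"}:
                raise PatternParseError(f"illegal residue in set {tok!r}", pos)
            elements.append(PatternElement("allowed", residues, min_rep, max_rep))
        elif body.startswith("{"):
            if not body.endswith("}") or len(body) < 3:
                raise PatternParseError(f"unbalanced or empty set in {tok!r}", pos)
            residues = frozenset(body[1:-1])
            if not residues <= AMINO_ACIDS | {"B", "Z"}:
                raise PatternParseError(f"illegal residue in set {tok!r}", pos)
            elements.append(PatternElement("forbidden", residues, min_rep, max_rep))
        elif len(body) == 1 and body in AMINO_ACIDS:
            elements.append(PatternElement("fixed", frozenset(body), min_rep, max_rep))
        else:
            raise PatternParseError(f"unrecognized element {tok!r}", pos)
        pos += len(tok) + 1
    return PrositePattern(accession, tuple(elements), n_anchor, c_anchor)


def _match_span(pattern: PrositePattern, seq: str, start: int, end: int) -> bool:
    """True iff seq[start:end] matches the full element list exactly."""

    def rec(ei: int, si: int) -> bool:
        if ei == len(pattern.elements):
            return si == end
        el = pattern.elements[ei]
        # try longer repetitions first (greedy), backtracking to min_rep
        hi = min(el.max_rep, end - si)
        if hi < el.min_rep:
            return False
        # verify matchability incrementally
        ok_upto = 0
        for k in range(hi):
            if el.matches(seq[si + k]):
                ok_upto = k + 1
            else:
                break
        for reps in range(min(hi, ok_upto), el.min_rep - 1, -1):
            if rec(ei + 1, si + reps):
                return True
        return False

    return rec(0, start)


def scan(pattern: PrositePattern, protein: str) -> list[SiteMatch]:
    """All maximal matches of *pattern* in *protein*, one per start position.

    For each start position admitting a match, the longest matching
    subsequence is reported (1-based inclusive coordinates). Overlapping
    matches from distinct start positions are all kept; output is ordered by
    start.
    """
    protein = protein.upper()
    if not protein:
        return []
    n = len(protein)
    out: list[SiteMatch] = []
    starts = [0] if pattern.n_anchor else range(n - pattern.min_length + 1)
    for s in starts:
        lo = s + pattern.min_length
        hi = min(n, s + pattern.max_length)
        if pattern.c_anchor:
            if hi < n or lo > n:
                # pattern cannot reach the C terminus from this start
                ends: list[int] = [n] if lo <= n <= hi else []
            else:
                ends = [n]
        else:
            ends = list(range(hi, lo - 1, -1))
        for e in ends:
            if _match_span(pattern, protein, s, e):
                out.append(SiteMatch(pattern.accession, s + 1, e, protein[s:e]))
                break
    return out


def detect_active_sites(
    protein: str, catalog: dict[str, PrositePattern]
) -> tuple[bool, bool]:
    """(glutamic-site present, cysteine-site present) for one protein.

    The catalog must contain patterns keyed ``PS00687`` (glutamic-acid active
    site) and ``PS00070`` (cysteine active site); a flag is true iff the scan
    yields at least one match.
    """
    for key in ("PS00687", "PS00070"):
        if key not in catalog:
            raise KeyError(f"pattern catalog missing required accession {key!r}")
    if not protein:
        return (False, False)
    glu = bool(scan(catalog["PS00687"], protein))
    cys = bool(scan(catalog["PS00070"], protein))
    return (glu, cys)


def load_pattern_catalog(path: str | Path) -> dict[str, PrositePattern]:
    """Read a flat ``accession=pattern`` config file into parsed patterns."""
    catalog: dict[str, PrositePattern] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        acc, _, pat = line.partition("=")
        catalog[acc.strip()] = parse_pattern(pat.strip(), accession=acc.strip())
    return catalog


def default_pattern_catalog() -> dict[str, PrositePattern]:
    """The bundled editable default patterns for PS00687 and PS00070."""
    ref = resources.files("genefam").joinpath("data/prosite_patterns.txt")
    with resources.as_file(ref) as p:
        return load_pattern_catalog(p)
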