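"""Family/subfamily assignment by pairwise identity and gene-symbol construction.

The nomenclature rules are the AGNC (ALDH Gene Nomenclature Committee)
identity criteria: a query protein more than 40% identical to a named
reference joins that reference's family, more than 60% identical joins its
subfamily as well; at or below 40% it founds a novel family. Identity is
computed over a global (Needleman–Wunsch, affine-gap) alignment, with the
full alignment length — gap columns included — as denominator. Both
thresholds and the denominator convention are configurable.

Gene symbols follow ``<prefix><root><family><subfamily letter><number><variant>``:
genes within a (family, subfamily) are numbered by chromosomal position
(chromosome, then start coordinate), and splice variants of a gene are
lettered ``a, b, c, ...`` in transcript-ID order; single-transcript genes
carry no variant letter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_model import GeneLocus, PipelineConfig, ValidationError, chromosome_of

__all__ = [
    "ReferenceEntry",
    "FamilyAssignment",
    "make_aligner",
    "global_align",
    "percent_identity",
    "align_identity",
    "assign_family",
    "build_symbol",
]


@dataclass(frozen=True)
class ReferenceEntry:
    """A named reference protein with known family and subfamily."""

    id: str
    sequence: str
    family: int
    subfamily: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"reference {self.id}: empty sequence")
        if self.family < 1:
            raise ValidationError(f"reference {self.id}: family must be >= 1")


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    best_reference: str
    identity: float
    family: int | Literal["novel"]
    subfamily: str  # single letter, or "new"

    @property
    def is_novel(self) -> bool:
        return self.family == "novel"


def make_aligner(
    matrix: str | None = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float = 1.0,
    mismatch: float = 0.0,
) -> Align.PairwiseAligner:
    """Global affine-gap aligner with the package's default scoring.

    ``matrix=None`` selects simple match/mismatch scoring (used in tests
    against a brute-force oracle); otherwise a named substitution matrix
    (default BLOSUM62) with gap open 10 / extend 0.5.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str, float]:
    """Optimal global alignment of two protein sequences.

    Returns ``(aligned_a, aligned_b, score)`` with ``-`` for gaps. The first
    alignment in the aligner's deterministic enumeration order is used, so
    repeated calls give identical tracebacks.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)
    best = aln[0]
    return str(best[0]), str(best[1]), best.score


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identical columns over the full alignment length (gaps included)."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences differ in length")
    if not aligned_a:
        raise ValidationError("empty alignment")
    ident = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return 100.0 * ident / len(aligned_a)


def align_identity(
    a: str,
    b: str,
    aligner: Align.PairwiseAligner | None = None,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> float:
    """Global-alignment percent identity between two sequences."""
    ga, gb, _ = global_align(a, b, aligner)
    if denominator == "shorter":
        ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
        return 100.0 * ident / min(len(a), len(b))
    return percent_identity(ga, gb)


def assign_family(
    query_id: str,
    query_seq: str,
    panel: Sequence[ReferenceEntry],
    config: PipelineConfig | None = None,
    aligner: Align.PairwiseAligner | None = None,
    used_subfamilies: dict[int, set[str]] | None = None,
) -> FamilyAssignment:
    """Assign family/subfamily for one query against a labelled panel.

    The best reference is the one of maximal identity (ties broken by lowest
    family number, then lexicographic reference ID). Identity above the
    subfamily threshold inherits family and subfamily; identity above only
    the family threshold inherits the family with the next unused subfamily
    letter; identity at or below the family threshold founds a novel family.
    Threshold comparisons are strict (``>``).
    """
    if not panel:
        raise ValidationError("reference panel is empty")
    config = config or PipelineConfig()
    if aligner is None:
        aligner = make_aligner()

    scored = [
        (align_identity(query_seq, ref.sequence, aligner), ref) for ref in panel
    ]
    best_ident, best_ref = max(
        scored, key=lambda t: (t[0], -t[1].family, _neg_lex(t[1].id))
    )

    if best_ident > config.subfamily_identity_threshold:
        family: int | str = best_ref.family
        subfamily = best_ref.subfamily
    elif best_ident > config.family_identity_threshold:
        family = best_ref.family
        taken = {r.subfamily for r in panel if r.family == best_ref.family}
        if used_subfamilies and best_ref.family in used_subfamilies:
            taken |= used_subfamilies[best_ref.family]
        subfamily = _next_letter(taken)
        if used_subfamilies is not None:
            used_subfamilies.setdefault(best_ref.family, set()).add(subfamily)
    else:
        family = "novel"
        subfamily = "new"
    return FamilyAssignment(query_id, best_ref.id, best_ident, family, subfamily)


def _next_letter(taken: set[str]) -> str:
    for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ":
        if c not in taken:
            return c
    raise ValidationError("all 26 subfamily letters exhausted")


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller ID."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def build_symbol(
    prefix: str,
    root: str,
    assignments: dict[str, FamilyAssignment],
    loci: dict[str, GeneLocus],
    variants: dict[str, Sequence[str]],
) -> dict[str, str]:
    """Construct gene symbols for every transcript.

    Parameters
    ----------
    assignments
        locus_id -> FamilyAssignment.
    loci
        locus_id -> GeneLocus (for chromosomal ordering).
    variants
        locus_id -> transcript IDs of that gene.

    Returns transcript_id -> symbol, e.g. ``SbALDH2B1a``. Novel families are
    labelled ``<prefix><root>novelK`` with a running index K.
    """
    symbols: dict[str, str] = {}
    groups: dict[tuple, list[str]] = {}
    novel_idx = 0
    novel_key: dict[str, int] = {}
    for lid, asn in assignments.items():
        if asn.is_novel:
            novel_idx += 1
            novel_key[lid] = novel_idx
            continue
        groups.setdefault((asn.family, asn.subfamily), []).append(lid)

    for (family, subfamily), members in groups.items():
        members.sort(
            key=lambda lid: (chromosome_of(loci[lid].locus_id, loci[lid].chromosome),
                             loci[lid].start)
        )
        for num, lid in enumerate(members, start=1):
            tids = sorted(variants[lid])
            if len(tids) > 26:
                raise ValidationError(f"{lid}: more than 26 splice variants")
            for vi, tid in enumerate(tids):
                letter = "" if len(tids) == 1 else "abcdefghijklmnopqrstuvwxyz"[vi]
                symbols[tid] = f"{prefix}{root}{family}{subfamily}{num}{letter}"

    for lid, k in novel_key.items():
        for tid in sorted(variants[lid]):
            symbols[tid] = f"{prefix}{root}novel{k}"
    return symbols
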