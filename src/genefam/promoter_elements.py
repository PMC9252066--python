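"""Promoter extraction and cis-regulatory element counting.

Promoters are the 1-kb (configurable) windows immediately 5' of a gene's
annotated start: bases ``[start-length, start-1]`` on the forward strand, or
the reverse complement of ``[end+1, end+length]`` for minus-strand genes
(1-based inclusive coordinates throughout). Windows truncated by a
chromosome end are returned shortened with a warning.

Element scanning matches IUPAC consensus strings on both strands; ``N`` in
the promoter matches nothing (conservative), positions are reported in
forward promoter coordinates, and overlapping occurrences of the same motif
are all counted. Summaries report, per element, the number of genes with at
least one occurrence, and per gene the total occurrence count and the number
of distinct element types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .core_model import GeneLocus, ValidationError, ValidationWarning, load_bundled_table

__all__ = [
    "MotifCatalogEntry",
    "ElementOccurrence",
    "IUPAC",
    "reverse_complement",
    "extract_upstream",
    "scan_elements",
    "summarize_elements",
    "load_motif_catalog",
    "default_motif_catalog",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifCatalogEntry:
    """A named cis-regulatory element with an IUPAC consensus."""

    name: str
    consensus: str
    category: Literal["phytohormone", "abiotic/biotic", "development/metabolism"]

    def __post_init__(self) -> None:
        if not self.consensus or any(c not in IUPAC for c in self.consensus.upper()):
            raise ValidationError(f"{self.name}: consensus must be IUPAC nucleotides")


@dataclass(frozen=True)
class ElementOccurrence:
    gene_id: str
    element: str
    strand: Literal["+", "-"]
    start: int  # 1-based, forward promoter coordinates


def extract_upstream(
    chromosome_seq: str,
    locus: GeneLocus,
    length: int = 1000,
    anchor: Literal["gene", "cds"] = "gene",
    cds_start: int | None = None,
) -> str:
    """The promoter window immediately 5' of *locus* on *chromosome_seq*.

    The anchor defaults to the annotated gene start; pass ``anchor="cds"``
    with ``cds_start`` to measure from the translation start instead.
    """
    if length <= 0:
        raise ValidationError("promoter length must be > 0")
    n = len(chromosome_seq)
    if not (1 <= locus.start <= locus.end <= n):
        raise ValidationError(
            f"{locus.locus_id}: coordinates outside the chromosome sequence"
        )
    if anchor == "cds" and cds_start is None:
        raise ValidationError("anchor='cds' requires cds_start")
    if locus.strand == "+":
        anchor_pos = locus.start if anchor == "gene" else cds_start
        lo = max(1, anchor_pos - length)
        hi = anchor_pos - 1
        promoter = chromosome_seq[lo - 1 : hi].upper()
    else:
        # minus strand: upstream lies at higher coordinates
        anchor_pos = locus.end if anchor == "gene" else cds_start
        lo = anchor_pos + 1
        hi = min(n, anchor_pos + length)
        promoter = reverse_complement(chromosome_seq[lo - 1 : hi])
    if len(promoter) < length:
        warnings.warn(
            f"{locus.locus_id}: promoter truncated to {len(promoter)} bp by the "
            "chromosome boundary",
            ValidationWarning,
            stacklevel=2,
        )
    return promoter


def _iupac_match(window: str, consensus: str) -> bool:
    # N in the *promoter* matches nothing
    return all(b != "N" and b in IUPAC[c] for b, c in zip(window, consensus))


def scan_elements(
    gene_id: str,
    promoter: str,
    catalog: Sequence[MotifCatalogEntry],
) -> list[ElementOccurrence]:
    """All IUPAC-aware occurrences of every catalog element on both strands."""
    if not catalog:
        raise ValidationError("motif catalog is empty")
    promoter = promoter.upper()
    occs: list[ElementOccurrence] = []
    for entry in catalog:
        cons = entry.consensus.upper()
        rc = reverse_complement(cons)
        k = len(cons)
        for i in range(len(promoter) - k + 1):
            window = promoter[i : i + k]
            if _iupac_match(window, cons):
                occs.append(ElementOccurrence(gene_id, entry.name, "+", i + 1))
            # palindromic consensi only count once per position
            if rc != cons and _iupac_match(window, rc):
                occs.append(ElementOccurrence(gene_id, entry.name, "-", i + 1))
    occs.sort(key=lambda o: (o.element, o.start, o.strand))
    return occs


def summarize_elements(
    occurrences: Iterable[ElementOccurrence],
    gene_set: Sequence[str],
    catalog: Sequence[MotifCatalogEntry],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate occurrence lists into the two reporting tables.

    Returns ``(per_element, per_gene)``: per element the number of genes with
    at least one occurrence (and total occurrences); per gene the total
    occurrence count and number of distinct element types.
    """
    occ_list = list(occurrences)
    by_gene: dict[str, list[ElementOccurrence]] = {g: [] for g in gene_set}
    for o in occ_list:
        if o.gene_id not in by_gene:
            raise ValidationError(f"occurrence for unknown gene {o.gene_id!r}")
        by_gene[o.gene_id].append(o)

    per_element = pd.DataFrame(
        [
            {
                "element": e.name,
                "category": e.category,
                "genes_with_element": sum(
                    1 for g in gene_set if any(o.element == e.name for o in by_gene[g])
                ),
                "total_occurrences": sum(1 for o in occ_list if o.element == e.name),
            }
            for e in catalog
        ]
    )
    per_gene = pd.DataFrame(
        [
            {
                "gene_id": g,
                "total_elements": len(by_gene[g]),
                "element_types": len({o.element for o in by_gene[g]}),
            }
            for g in gene_set
        ]
    )
    return per_element, per_gene


def load_motif_catalog(path: str | Path) -> list[MotifCatalogEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifCatalogEntry(str(r["name"]), str(r["consensus"]), str(r["category"]))
        for _, r in df.iterrows()
    ]


def default_motif_catalog() -> list[MotifCatalogEntry]:
    """The bundled editable PlantCARE-style element catalog."""
    df = load_bundled_table("plantcare_catalog.tsv")
    return [
        MotifCatalogEntry(str(r["name"]), str(r["consensus"]), str(r["category"]))
        for _, r in df.iterrows()
    ]
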