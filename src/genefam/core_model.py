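"""Shared domain types, configuration, readers/writers, and validation.

Conventions used throughout the package:

* Genomic coordinates are **1-based inclusive on both ends** (the convention of
  Phytozome locus records). All interval arithmetic in downstream modules
  assumes this.
* Chromosome numbers are parsed from Phytozome-style locus identifiers
  (``Sobic.004G250900`` -> chromosome 4) unless an explicit chromosome label
  is supplied, in which case the explicit label wins.
* A gene locus may carry several transcript models (splice variants); a
  transcript's protein length must equal ``CDS/3 - 1`` (terminal stop codon
  excluded from the peptide).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "ValidationError",
    "ValidationWarning",
    "GeneLocus",
    "TranscriptModel",
    "PipelineConfig",
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
    "read_fasta",
    "write_fasta",
    "chromosome_of",
    "read_gene_table",
    "write_gene_table",
    "gene_table_to_records",
    "records_to_gene_table",
    "load_bundled_table",
    "GENE_TABLE_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


class ValidationWarning(UserWarning):
    """Emitted for recoverable problems on user-supplied data (non-strict mode)."""


#: Amino-acid alphabet: the 20 standard residues plus the ambiguity codes B/Z/X
#: and ``*`` for a stop, ``-`` for an alignment gap.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*-")

#: Nucleotide alphabet: the four bases plus N, and ``-`` for an alignment gap.
DNA_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class GeneLocus:
    """A gene locus with 1-based inclusive genomic coordinates."""

    locus_id: str
    chromosome: str
    strand: Literal["+", "-"]
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus_id must be non-empty")
        if not self.chromosome:
            raise ValidationError(f"{self.locus_id}: chromosome label must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.locus_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValidationError(
                f"{self.locus_id}: start ({self.start}) > end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript (splice variant) of a gene locus.

    ``cds`` and ``protein`` sequences are optional — coordinate tables carry
    only their lengths — but when both are present the peptide must be the
    translation of the CDS minus the terminal stop.
    """

    transcript_id: str
    parent: str
    transcript_len: int
    cds_len: int
    protein_len: int
    cds: str | None = None
    protein: str | None = None
    domain_span: tuple[int, int] | None = None
    glutamic_site: bool | None = None
    cysteine_site: bool | None = None
    annotation: str | None = None
    mw_kda: float | None = None
    pi: float | None = None
    localization: str | None = None

    def validate(self, strict: bool = True) -> list[str]:
        """Check structural invariants; return problem descriptions.

        In strict mode any problem raises :class:`ValidationError`; otherwise
        problems are returned (and emitted as :class:`ValidationWarning`).
        """
        problems: list[str] = []
        if self.cds_len % 3 != 0:
            # length divisibility is always fatal: downstream codon arithmetic
            # is meaningless without it
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_len} not divisible by 3"
            )
        if self.protein_len != self.cds_len // 3 - 1:
            problems.append(
                f"{self.transcript_id}: protein length {self.protein_len} != "
                f"CDS/3 - 1 = {self.cds_len // 3 - 1}"
            )
        if self.domain_span is not None:
            lo, hi = self.domain_span
            if not (1 <= lo <= hi <= self.protein_len):
                problems.append(
                    f"{self.transcript_id}: domain span {self.domain_span} outside "
                    f"[1, {self.protein_len}]"
                )
        if self.cds is not None and len(self.cds) != self.cds_len:
            problems.append(f"{self.transcript_id}: cds sequence length mismatch")
        if self.protein is not None and len(self.protein) != self.protein_len:
            problems.append(f"{self.transcript_id}: protein sequence length mismatch")
        if problems and strict:
            raise ValidationError("; ".join(problems))
        for p in problems:
            warnings.warn(p, ValidationWarning, stacklevel=2)
        return problems


@dataclass
class PipelineConfig:
    """Tunable thresholds and rates for every pipeline stage.

    Defaults follow the published workflow: family/subfamily identity cut-offs
    of 40%/60% (AGNC nomenclature rules), a 100-kb window for tandem
    duplication, a 90% identity flag for the strict segmental rule, a neutral
    substitution rate λ of 6.1e-9 substitutions/site/year for dating, 1-kb
    promoters, and a 60% of-row-maximum threshold for calling a gene "highly
    expressed" in a tissue.
    """

    family_identity_threshold: float = 40.0
    subfamily_identity_threshold: float = 60.0
    tandem_window: int = 100_000
    segmental_identity_threshold: float = 90.0
    substitution_rate: float = 6.1e-9
    promoter_length: int = 1000
    high_expression_threshold: float = 60.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "family_identity_threshold",
            "subfamily_identity_threshold",
            "segmental_identity_threshold",
            "high_expression_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValidationError(f"{name} must be in (0, 100], got {v}")
        if self.substitution_rate <= 0:
            raise ValidationError("substitution_rate must be > 0")
        if self.promoter_length <= 0:
            raise ValidationError("promoter_length must be > 0")
        if self.tandem_window <= 0:
            raise ValidationError("tandem_window must be > 0")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    alphabet: Literal["protein", "dna"] | frozenset | None = None,
) -> list[tuple[str, str]]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased and record order is preserved. Duplicate IDs and
    characters outside the declared alphabet are errors.
    """
    from Bio import SeqIO

    if alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    elif alphabet == "dna":
        allowed = DNA_ALPHABET
    else:
        allowed = alphabet

    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA ID: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if allowed is not None:
            for i, ch in enumerate(seq):
                if ch not in allowed:
                    raise ValidationError(
                        f"record {rec.id!r}: illegal character {ch!r} at position {i + 1}"
                    )
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Locus-ID parsing
# ---------------------------------------------------------------------------

_SOBIC_RE = re.compile(r"^[A-Za-z]+\.(\d{3})G\d+")
_CHR_RE = re.compile(r"^(?:Chr|chr|chromosome)?0*(\d+)$")


def chromosome_of(locus_id: str, explicit: str | None = None) -> int:
    """Chromosome number of a locus.

    An explicit chromosome label (``"Chr02"``, ``"2"``) takes precedence;
    otherwise the three digits after the genome prefix of a Phytozome-style
    ID (``Sobic.004G250900`` -> 4) are parsed.
    """
    if explicit is not None and str(explicit).strip():
        m = _CHR_RE.match(str(explicit).strip())
        if not m:
            raise ValidationError(f"unparseable chromosome label {explicit!r}")
        return int(m.group(1))
    m = _SOBIC_RE.match(locus_id)
    if not m:
        raise ValidationError(
            f"cannot derive chromosome from locus ID {locus_id!r} and no explicit "
            "chromosome column was given"
        )
    return int(m.group(1))


# ---------------------------------------------------------------------------
# Gene-table I/O
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = [
    "family",
    "locus_id",
    "transcript_id",
    "name",
    "chromosome",
    "start",
    "end",
    "strand",
    "transcript_nt",
    "cds_nt",
    "protein_aa",
    "domain_start",
    "domain_end",
    "ps00687",
    "ps00070",
    "mw_kda",
    "pi",
    "localization",
]

_REQUIRED = {"family", "locus_id", "transcript_id", "start", "end", "cds_nt", "protein_aa"}


def read_gene_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a tab-separated gene/transcript coordinate table.

    The table mirrors the columns of a per-transcript annotation table:
    one row per transcript, 1-based inclusive coordinates. A ``chromosome``
    column is derived from locus IDs when absent, and a ``strand`` column
    defaults to ``"+"``. Row invariants are enforced via
    :class:`TranscriptModel` (fatal in strict mode, warnings otherwise).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"locus_id": str, "transcript_id": str})
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValidationError(f"gene table missing required columns: {sorted(missing)}")
    if "chromosome" not in df.columns:
        df["chromosome"] = [f"Chr{chromosome_of(lid):02d}" for lid in df["locus_id"]]
    else:
        df["chromosome"] = [
            f"Chr{chromosome_of(lid, explicit=chrom):02d}"
            for lid, chrom in zip(df["locus_id"], df["chromosome"])
        ]
    if "strand" not in df.columns:
        df["strand"] = "+"
    df["strand"] = df["strand"].fillna("+")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValidationError(f"duplicate transcript IDs: {dups}")
    for rec in gene_table_to_records(df):
        rec[1].validate(strict=strict)
    return df


def write_gene_table(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in GENE_TABLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def gene_table_to_records(df: pd.DataFrame) -> list[tuple[GeneLocus, TranscriptModel]]:
    """Convert a gene-table DataFrame into typed (locus, transcript) pairs."""
    out: list[tuple[GeneLocus, TranscriptModel]] = []
    for row in df.itertuples(index=False):
        locus = GeneLocus(
            locus_id=row.locus_id,
            chromosome=str(getattr(row, "chromosome", "") or f"Chr{chromosome_of(row.locus_id):02d}"),
            strand=str(getattr(row, "strand", "+") or "+"),
            start=int(row.start),
            end=int(row.end),
        )
        dom = None
        ds, de = getattr(row, "domain_start", None), getattr(row, "domain_end", None)
        if ds is not None and de is not None and not pd.isna(ds) and not pd.isna(de):
            dom = (int(ds), int(de))

        def _flag(v):
            if v is None or (isinstance(v, float) and pd.isna(v)):
                return None
            return str(v).strip().lower() in ("yes", "true", "1")

        tm = TranscriptModel(
            transcript_id=row.transcript_id,
            parent=row.locus_id,
            transcript_len=int(getattr(row, "transcript_nt", 0) or 0),
            cds_len=int(row.cds_nt),
            protein_len=int(row.protein_aa),
            domain_span=dom,
            glutamic_site=_flag(getattr(row, "ps00687", None)),
            cysteine_site=_flag(getattr(row, "ps00070", None)),
            annotation=getattr(row, "name", None),
            mw_kda=float(row.mw_kda) if hasattr(row, "mw_kda") and not pd.isna(row.mw_kda) else None,
            pi=float(row.pi) if hasattr(row, "pi") and not pd.isna(row.pi) else None,
            localization=getattr(row, "localization", None),
        )
        out.append((locus, tm))
    return out


def records_to_gene_table(records: Iterable[tuple[GeneLocus, TranscriptModel]]) -> pd.DataFrame:
    rows = []
    for locus, tm in records:
        rows.append(
            {
                "locus_id": locus.locus_id,
                "transcript_id": tm.transcript_id,
                "name": tm.annotation,
                "chromosome": locus.chromosome,
                "start": locus.start,
                "end": locus.end,
                "strand": locus.strand,
                "transcript_nt": tm.transcript_len,
                "cds_nt": tm.cds_len,
                "protein_aa": tm.protein_len,
                "domain_start": tm.domain_span[0] if tm.domain_span else None,
                "domain_end": tm.domain_span[1] if tm.domain_span else None,
                "ps00687": None if tm.glutamic_site is None else ("Yes" if tm.glutamic_site else "No"),
                "ps00070": None if tm.cysteine_site is None else ("Yes" if tm.cysteine_site else "No"),
                "mw_kda": tm.mw_kda,
                "pi": tm.pi,
                "localization": tm.localization,
            }
        )
    return pd.DataFrame(rows)


def load_bundled_table(name: str) -> pd.DataFrame:
    """Load a bundled data table by file name (e.g. ``"table1.tsv"``)."""
    ref = resources.files("genefam").joinpath("data").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")
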