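"""Duplicate-pair classification, Nei–Gojobori Ka/Ks, selection calls, dating.

Duplication class
    A homologous gene pair is *tandem* when both loci sit on the same
    chromosome with an inter-gene gap of at most 100 kb (configurable);
    otherwise it is *segmental*. An optional strict mode additionally
    requires >90% protein identity for the segmental label.

Ka/Ks (Nei & Gojobori 1986 counting with Jukes–Cantor correction)
    Synonymous/nonsynonymous *sites* per codon are the expected fractions of
    the three possible single-nucleotide changes at each position that
    preserve the encoded amino acid; changes creating stop codons are
    excluded from both numerator and denominator at that position.
    *Differences* between two codons are averaged over all minimal
    substitution pathways (1, 2 or 6 orderings for 1/2/3 changed positions),
    dropping pathways that pass through a stop codon. Proportions
    pS = Sd/S and pN = Nd/N are corrected for multiple hits with
    JC(p) = -(3/4)·ln(1 - 4p/3); Ka/Ks > 1, < 1 and = 1 indicate positive,
    purifying and neutral selection.

Dating
    T = Ks / (2λ), reported in Mya; λ defaults to 6.1e-9
    substitutions/site/year via :class:`~genefam.core_model.PipelineConfig`.

Reported numbers are **truncated** (not rounded) to 4 decimals for Ka, Ks and
Ka/Ks and 2 decimals for times, matching the reporting convention of the
reference tables this module reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Literal, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .core_model import GeneLocus, PipelineConfig, ValidationError

__all__ = [
    "DuplicatePair",
    "CodonAlignment",
    "classify_pair",
    "ng86_sites",
    "ng86_differences",
    "build_codon_alignment",
    "kaks",
    "compute_ratio",
    "divergence_time",
    "selection_regime",
    "jukes_cantor",
    "truncate",
    "UNDEFINED",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"

#: Sentinel for an undefined ratio/time (e.g. Ks = 0).
UNDEFINED = float("nan")


def _is_undefined(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class DuplicatePair:
    """One duplicated gene pair with its evolutionary statistics."""

    locus_a: str
    locus_b: str
    protein_identity: float | None
    ka: float
    ks: float
    ratio: float  # NaN when undefined
    dup_class: Literal["tandem", "segmental"]
    time_mya: float  # NaN when not determinable


@dataclass(frozen=True)
class CodonAlignment:
    """Paired gap-free codon columns from two coding sequences."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValidationError("codon alignment: unequal codon counts")
        for c in self.codons_a + self.codons_b:
            if len(c) != 3:
                raise ValidationError(f"not a codon: {c!r}")
            if c in _STOPS:
                raise ValidationError(f"internal stop codon {c!r} in alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


# ---------------------------------------------------------------------------
# Duplication classification
# ---------------------------------------------------------------------------

def classify_pair(
    locus_a: GeneLocus,
    locus_b: GeneLocus,
    config: PipelineConfig | None = None,
    protein_identity: float | None = None,
    strict_segmental: bool = False,
) -> str:
    """Classify a homologous pair as ``"tandem"`` or ``"segmental"``.

    Tandem: same chromosome and inter-gene gap (upstream end to downstream
    start; 0 for overlapping spans) within the configured window. Everything
    else is segmental; with ``strict_segmental`` the segmental label
    additionally requires protein identity above the configured 90% cut-off,
    and pairs failing both tests raise.
    """
    config = config or PipelineConfig()
    if locus_a.locus_id == locus_b.locus_id:
        raise ValidationError(f"cannot classify {locus_a.locus_id} against itself")
    if locus_a.chromosome == locus_b.chromosome:
        up, down = sorted((locus_a, locus_b), key=lambda l: l.start)
        gap = max(0, down.start - up.end)
        if gap <= config.tandem_window:
            return "tandem"
    if strict_segmental:
        if protein_identity is None:
            raise ValidationError("strict segmental rule requires protein identity")
        if protein_identity <= config.segmental_identity_threshold:
            raise ValidationError(
                f"{locus_a.locus_id}/{locus_b.locus_id}: neither tandem nor >"
                f"{config.segmental_identity_threshold}% identical"
            )
    return "segmental"


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValidationError(f"ambiguous or malformed codon {codon!r}")
    if codon in _STOPS:
        raise ValidationError(f"stop codon {codon!r} not allowed")


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one codon; sums to 3.

    Per position, the synonymous fraction is the share of the possible
    single-nucleotide changes that preserve the amino acid, with changes to
    stop codons removed from both numerator and denominator.
    """
    codon = codon.upper()
    _check_codon(codon)
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            n_valid += 1
            if _CODON_TABLE[alt] == aa:
                n_syn += 1
        syn += n_syn / n_valid if n_valid else 0.0
    return syn, 3.0 - syn


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal substitution pathways between the codons,
    excluding pathways whose intermediates are stop codons. When every
    pathway is stop-blocked (possible only for 2–3 differences), the average
    is taken over all pathways regardless of stops, so the difference count
    is still conserved.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    _check_codon(codon_a)
    _check_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def pathway_counts(order: tuple[int, ...], allow_stops: bool):
        cur = codon_a
        syn = nonsyn = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops:
                return None
            aa_cur = _CODON_TABLE.get(cur)
            aa_nxt = _CODON_TABLE.get(nxt)
            if aa_cur == aa_nxt and aa_cur is not None:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    orders = list(permutations(diff_pos))
    counted = [c for o in orders if (c := pathway_counts(o, False)) is not None]
    if not counted:
        counted = [pathway_counts(o, True) for o in orders]
    syn = sum(c[0] for c in counted) / len(counted)
    nonsyn = sum(c[1] for c in counted) / len(counted)
    return syn, nonsyn


def build_codon_alignment(
    cds_a: str, cds_b: str, protein_alignment: tuple[str, str] | None = None
) -> CodonAlignment:
    """Thread two CDS onto a protein alignment and drop gap codon columns.

    Without an explicit protein alignment the CDS must be equal-length and
    are paired codon-by-codon. Terminal stop codons are trimmed.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for name, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3:
            raise ValidationError(f"CDS {name} length not divisible by 3")

    def codons(cds: str) -> list[str]:
        cs = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if cs and cs[-1] in _STOPS:
            cs = cs[:-1]
        return cs

    ca, cb = codons(cds_a), codons(cds_b)
    if protein_alignment is None:
        if len(ca) != len(cb):
            raise ValidationError(
                "equal-length CDS required when no protein alignment is given"
            )
        pairs = list(zip(ca, cb))
    else:
        pa, pb = protein_alignment
        if len(pa) != len(pb):
            raise ValidationError("protein alignment rows differ in length")
        if len(pa.replace("-", "")) != len(ca) or len(pb.replace("-", "")) != len(cb):
            raise ValidationError("protein alignment does not match CDS lengths")
        ia = ib = 0
        pairs = []
        for x, y in zip(pa, pb):
            if x != "-" and y != "-":
                pairs.append((ca[ia], cb[ib]))
            if x != "-":
                ia += 1
            if y != "-":
                ib += 1
    # codon columns containing ambiguity are dropped rather than guessed
    pairs = [
        (x, y)
        for x, y in pairs
        if all(b in _BASES for b in x + y) and x not in _STOPS and y not in _STOPS
    ]
    return CodonAlignment(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - 4p/3)."""
    if p < 0:
        raise ValidationError("proportion must be >= 0")
    if p >= 0.75:
        return UNDEFINED  # saturated
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str] | None = None,
) -> tuple[float, float, float]:
    """(Ka, Ks, Ka/Ks) for a pair of coding sequences by NG86 + JC.

    Sites are averaged over the two sequences; the ratio is NaN when Ks = 0
    or either rate is saturated.
    """
    aln = build_codon_alignment(cds_a, cds_b, protein_alignment)
    if aln.n_codons == 0:
        raise ValidationError("no comparable codons")
    S = N = Sd = Nd = 0.0
    for x, y in zip(aln.codons_a, aln.codons_b):
        sx, nx = ng86_sites(x)
        sy, ny = ng86_sites(y)
        S += (sx + sy) / 2.0
        N += (nx + ny) / 2.0
        ds, dn = ng86_differences(x, y)
        Sd += ds
        Nd += dn
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    return ka, ks, compute_ratio(ka, ks)


def compute_ratio(ka: float, ks: float) -> float:
    """Ka/Ks; NaN when Ks = 0 or either rate is undefined."""
    if _is_undefined(ka) or _is_undefined(ks):
        return UNDEFINED
    if ka < 0 or ks < 0:
        raise ValidationError("rates must be non-negative")
    if ks == 0:
        return UNDEFINED
    return ka / ks


def divergence_time(ks: float, rate: float | None = None) -> float:
    """Duplication age T = Ks/(2λ) in Mya; NaN for undefined Ks."""
    if rate is None:
        rate = PipelineConfig().substitution_rate
    if rate <= 0:
        raise ValidationError("substitution rate must be > 0")
    if _is_undefined(ks):
        return UNDEFINED
    if ks < 0:
        raise ValidationError("Ks must be >= 0")
    return ks / (2.0 * rate) / 1e6


def selection_regime(ratio: float, tol: float = 1e-9) -> str:
    """Interpret a Ka/Ks ratio: positive (>1), purifying (<1), neutral (=1)."""
    if _is_undefined(ratio):
        return "undetermined"
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at the given number of decimals (reporting rule)."""
    if _is_undefined(x):
        return x
    factor = 10 ** decimals
    return math.trunc(x * factor) / factor
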