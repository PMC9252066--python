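"""Protein molecular weight, isoelectric point, and summary statistics.

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), reported in kDa. The isoelectric point is the pH of zero net
charge under the Henderson–Hasselbalch model

    charge(pH) = Σ_basic 10^pKa/(10^pKa + 10^pH) − Σ_acidic 10^pH/(10^pKa + 10^pH)

over the termini and the ionizable side chains (D, E, C, Y, H, K, R), solved
by bisection on [0, 14]; the default pKa values are the Bjellqvist set used
by common proteomics calculators. Summary statistics (min/max/mean of
length, MW, pI) report means rounded half-up at the stated precision, the
convention of the annotation tables this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .core_model import ValidationError

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "BJELLQVIST",
    "PkaSet",
    "protein_mw",
    "protein_pi",
    "net_charge",
    "round_half_up",
    "summarize_physico",
]

#: Average (isotope-abundance weighted) residue masses in Da, i.e. the
#: monomer mass minus one water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153

#: Mean of the 20 residue masses, used for X only when explicitly enabled.
_MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class PkaSet:
    """Named pKa set for the termini and ionizable side chains."""

    name: str
    n_terminus: float
    c_terminus: float
    acidic: Mapping[str, float]  # D, E, C, Y side chains
    basic: Mapping[str, float]   # H, K, R side chains

    def __post_init__(self) -> None:
        for v in (self.n_terminus, self.c_terminus, *self.acidic.values(), *self.basic.values()):
            if not 0 < v < 14:
                raise ValidationError(f"pKa {v} outside (0, 14)")


#: The Bjellqvist pKa values (as used by the ProtParam-style calculators).
BJELLQVIST = PkaSet(
    name="bjellqvist",
    n_terminus=7.5,
    c_terminus=3.55,
    acidic={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    basic={"H": 5.98, "K": 10.0, "R": 12.0},
)


def protein_mw(
    sequence: str,
    mass_table: Mapping[str, float] | None = None,
    allow_x: bool = False,
) -> float:
    """Average molecular weight of a peptide in kDa."""
    if not sequence:
        raise ValidationError("empty sequence")
    table = dict(mass_table or AVERAGE_RESIDUE_MASS)
    total = WATER_MASS
    for i, aa in enumerate(sequence.upper()):
        if aa not in table:
            if aa == "X" and allow_x:
                total += _MEAN_RESIDUE_MASS
                continue
            raise ValidationError(f"unknown residue {aa!r} at position {i + 1}")
        total += table[aa]
    return total / 1000.0


def net_charge(sequence: str, ph: float, pka: PkaSet = BJELLQVIST) -> float:
    """Net charge of the peptide at the given pH."""
    seq = sequence.upper()
    charge = 10 ** pka.n_terminus / (10 ** pka.n_terminus + 10 ** ph)
    charge -= 10 ** ph / (10 ** pka.c_terminus + 10 ** ph)
    for aa, val in pka.basic.items():
        n = seq.count(aa)
        if n:
            charge += n * 10 ** val / (10 ** val + 10 ** ph)
    for aa, val in pka.acidic.items():
        n = seq.count(aa)
        if n:
            charge -= n * 10 ** ph / (10 ** val + 10 ** ph)
    return charge


def protein_pi(
    sequence: str, pka: PkaSet = BJELLQVIST, tol: float = 1e-4
) -> float:
    """Isoelectric point by bisection of the monotone net-charge function."""
    if not sequence:
        raise ValidationError("empty sequence")
    lo, hi = 0.0, 14.0
    # charge is strictly decreasing in pH, positive at pH 0, negative at 14
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(sequence, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up at the given precision (reporting convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_physico(records: pd.DataFrame) -> dict[str, dict[str, float]]:
    """min/max/mean summaries for protein length, MW, and pI.

    *records* needs columns ``protein_aa``, ``mw_kda``, ``pi``. Means are
    rounded half-up at the reporting precision (0 dp for length, 2 dp for MW
    and pI); minima and maxima are exact.
    """
    if records.empty:
        raise ValidationError("no records to summarize")
    out: dict[str, dict[str, float]] = {}
    for col, key, dp in (
        ("protein_aa", "length_aa", 0),
        ("mw_kda", "mw_kda", 2),
        ("pi", "pi", 2),
    ):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
        vals = records[col].astype(float)
        out[key] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": round_half_up(float(vals.mean()), dp),
        }
    return out
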