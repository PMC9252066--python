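"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed (a dedicated
:class:`numpy.random.Generator` per call, no global state) and returns its
outputs together with a :class:`TruthManifest` recording the planted
parameters, so recovery tests can compare pipeline output against truth.

What the generators emulate — and deliberately do not:

* ``simulate_family_panel`` plants proteins at controlled pairwise identity
  by substitution-only mutation of family ancestors (no indels, uniform
  residue usage), straddling the 40%/60% nomenclature thresholds.
* ``simulate_duplication_set`` plants exact counts of synonymous and
  nonsynonymous single-nucleotide substitutions into stop-free random CDS
  (at most one substitution per codon; no codon-usage bias), plus gene
  coordinates realizing tandem (same chromosome, gap below the window) and
  segmental (different chromosomes) layouts.
* ``simulate_promoters`` builds motif-free background (iterative rejection
  repair against the catalog, both strands) and plants exact occurrence
  counts of catalog consensi at non-overlapping positions.
* ``simulate_expression`` builds group-mean × gene-effect matrices with
  multiplicative lognormal noise, and Cq tables whose ΔΔCt encodes planted
  fold changes with Gaussian cycle noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .agnc_nomenclature import ReferenceEntry
from .core_model import GeneLocus, ValidationError
from .duplication_evolution import _BASES, _CODON_TABLE, _STOPS
from .promoter_elements import (
    IUPAC,
    MotifCatalogEntry,
    reverse_complement,
    scan_elements,
)

__all__ = [
    "TruthManifest",
    "simulate_family_panel",
    "simulate_duplication_set",
    "simulate_promoters",
    "simulate_expression",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TruthManifest:
    """Planted ground truth for one generator call."""

    generator: str
    seed: int
    entries: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed, "entries": self.entries},
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Family panel
# ---------------------------------------------------------------------------

def simulate_family_panel(
    n_families: int,
    members_per_family: int,
    identity_levels: Sequence[float],
    seed: int,
    length: int = 300,
) -> tuple[list[tuple[str, str]], list[ReferenceEntry], TruthManifest]:
    """Reference panel plus query proteins at planted pairwise identities.

    One random ancestor per family forms the labelled panel (subfamily "A");
    each query is the ancestor with exactly ``round((1 - p/100) * length)``
    positions substituted, so the realized ungapped identity equals the
    requested level to within 1/length. Levels below 5% are rejected as
    infeasible (indistinguishable from background identity).
    """
    if length < 100:
        raise ValidationError("ancestor length must be >= 100 aa")
    for p in identity_levels:
        if not 5 <= p < 100:
            raise ValidationError(f"infeasible identity level {p}")
    rng = np.random.default_rng(seed)
    panel: list[ReferenceEntry] = []
    queries: list[tuple[str, str]] = []
    entries: dict[str, Any] = {}
    for f in range(1, n_families + 1):
        ancestor = "".join(rng.choice(list(_AA), size=length))
        ref_id = f"REF{f}A"
        panel.append(ReferenceEntry(ref_id, ancestor, f, "A"))
        for m in range(members_per_family):
            level = float(identity_levels[m % len(identity_levels)])
            k = round((1 - level / 100.0) * length)
            pos = rng.choice(length, size=k, replace=False)
            seq = list(ancestor)
            for p_ in pos:
                choices = [a for a in _AA if a != seq[p_]]
                seq[p_] = choices[rng.integers(len(choices))]
            qid = f"Q.f{f}.m{m + 1}"
            queries.append((qid, "".join(seq)))
            entries[qid] = {
                "family": f,
                "reference": ref_id,
                "identity_level": level,
                "realized_identity": 100.0 * (length - k) / length,
                "n_substitutions": int(k),
            }
    manifest = TruthManifest("family_panel", seed, entries)
    return queries, panel, manifest


# ---------------------------------------------------------------------------
# Duplication set
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    sense = sorted(set(_CODON_TABLE) - _STOPS)
    # avoid Met/Trp-free requirements; any stop-free codon stream is fine
    return [sense[i] for i in rng.integers(len(sense), size=n_codons)]


def _single_nt_variants(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1 :])
    return out


def simulate_duplication_set(
    n_pairs: int,
    codons: int,
    syn_subs: int,
    nonsyn_subs: int,
    layout: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str, str]], dict[str, GeneLocus], TruthManifest]:
    """CDS pairs with exact planted substitution counts plus a genomic layout.

    Returns ``(pairs, loci, manifest)`` where each pair is
    ``(id_a, cds_a, id_b, cds_b)``; ``layout`` gives each pair's true
    duplication class (``"tandem"``/``"segmental"``, default alternating).
    At most one substitution is planted per codon: synonymous changes go to
    codons with a synonymous single-nucleotide neighbour, nonsynonymous
    changes to any remaining codon (never creating stops).
    """
    if codons < 50:
        raise ValidationError("need at least 50 codons")
    if syn_subs + nonsyn_subs > codons:
        raise ValidationError("substitution budget exceeds one per codon")
    layout = list(layout) if layout is not None else [
        "tandem" if i % 2 == 0 else "segmental" for i in range(n_pairs)
    ]
    if len(layout) != n_pairs:
        raise ValidationError("layout length must equal n_pairs")
    rng = np.random.default_rng(seed)

    pairs: list[tuple[str, str, str, str]] = []
    loci: dict[str, GeneLocus] = {}
    entries: dict[str, Any] = {}
    for i in range(n_pairs):
        anc = _random_cds(rng, codons)
        derived = list(anc)
        # codons admitting a synonymous non-stop neighbour
        syn_ok = [
            ci
            for ci, c in enumerate(anc)
            if any(
                v not in _STOPS and _CODON_TABLE[v] == _CODON_TABLE[c]
                for v in _single_nt_variants(c)
            )
        ]
        if len(syn_ok) < syn_subs:
            raise ValidationError("not enough synonymous-capable codons")
        syn_sites = list(rng.choice(syn_ok, size=syn_subs, replace=False))
        remaining = [ci for ci in range(codons) if ci not in set(syn_sites)]
        nonsyn_ok = [
            ci
            for ci in remaining
            if any(
                v not in _STOPS and _CODON_TABLE[v] != _CODON_TABLE[anc[ci]]
                for v in _single_nt_variants(anc[ci])
            )
        ]
        if len(nonsyn_ok) < nonsyn_subs:
            raise ValidationError("not enough nonsynonymous-capable codons")
        nonsyn_sites = list(rng.choice(nonsyn_ok, size=nonsyn_subs, replace=False))
        for ci in syn_sites:
            opts = [
                v
                for v in _single_nt_variants(anc[ci])
                if v not in _STOPS and _CODON_TABLE[v] == _CODON_TABLE[anc[ci]]
            ]
            derived[ci] = opts[rng.integers(len(opts))]
        for ci in nonsyn_sites:
            opts = [
                v
                for v in _single_nt_variants(anc[ci])
                if v not in _STOPS and _CODON_TABLE[v] != _CODON_TABLE[anc[ci]]
            ]
            derived[ci] = opts[rng.integers(len(opts))]

        id_a, id_b = f"dup{i + 1}a", f"dup{i + 1}b"
        pairs.append((id_a, "".join(anc), id_b, "".join(derived)))
        gene_len = 3 * codons
        if layout[i] == "tandem":
            chrom = f"Chr{(i % 9) + 1:02d}"
            start_a = 1_000_000 * (i + 1)
            start_b = start_a + gene_len + 30_000  # 30-kb gap, inside the window
            loci[id_a] = GeneLocus(id_a, chrom, "+", start_a, start_a + gene_len - 1)
            loci[id_b] = GeneLocus(id_b, chrom, "+", start_b, start_b + gene_len - 1)
        else:
            start = 1_000_000 * (i + 1)
            loci[id_a] = GeneLocus(id_a, f"Chr{(i % 5) + 1:02d}", "+", start, start + gene_len - 1)
            loci[id_b] = GeneLocus(id_b, f"Chr{(i % 5) + 6:02d}", "+", start, start + gene_len - 1)
        entries[f"{id_a}|{id_b}"] = {
            "syn_subs": int(syn_subs),
            "nonsyn_subs": int(nonsyn_subs),
            "n_codons": int(codons),
            "dup_class": layout[i],
        }
    return pairs, loci, TruthManifest("duplication_set", seed, entries)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in consensus.upper())


def simulate_promoters(
    n_genes: int,
    catalog: Sequence[MotifCatalogEntry],
    plant_counts: Mapping[str, Mapping[str, int]],
    length: int = 1000,
    seed: int = 0,
    max_tries: int = 50,
) -> tuple[list[tuple[str, str]], TruthManifest]:
    """Promoter sequences carrying exactly the requested motif occurrences.

    ``plant_counts`` maps gene ID -> {element name: count}; remaining catalog
    elements occur zero times. Backgrounds are repaired by re-randomizing any
    window matching the catalog until clean; plants are verified by a full
    re-scan, retrying with fresh positions when junction effects or motif
    nesting (e.g. one consensus containing another) change realized counts —
    inherently conflicting requests exhaust ``max_tries`` and raise.
    """
    by_name = {e.name: e for e in catalog}
    for g, wants in plant_counts.items():
        for el, cnt in wants.items():
            if el not in by_name:
                raise ValidationError(f"{g}: unknown element {el!r}")
            if cnt * (len(by_name[el].consensus) + 2) > length:
                raise ValidationError(f"{g}: requested plants exceed promoter capacity")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def clean_background() -> str:
        seq = list(rng.choice(bases, size=length))
        for _ in range(500):
            occs = scan_elements("bg", "".join(seq), catalog)
            if not occs:
                return "".join(seq)
            for o in occs:
                k = len(by_name[o.element].consensus)
                for p in range(o.start - 1, o.start - 1 + k):
                    seq[p] = bases[rng.integers(4)]
        raise ValidationError("could not generate motif-free background")

    promoters: list[tuple[str, str]] = []
    entries: dict[str, Any] = {}
    for gi in range(n_genes):
        gene = f"G{gi + 1}"
        wants = dict(plant_counts.get(gene, {}))
        want_total = {e.name: wants.get(e.name, 0) for e in catalog}
        placed_record = None
        for _ in range(max_tries):
            seq = list(clean_background())
            taken: list[tuple[int, int]] = []
            placements = []
            ok = True
            for el, cnt in wants.items():
                k = len(by_name[el].consensus)
                for _c in range(cnt):
                    for _t in range(200):
                        pos = int(rng.integers(length - k + 1))
                        if all(pos + k <= s or pos >= e for s, e in taken):
                            break
                    else:
                        ok = False
                        break
                    strand = "+" if rng.random() < 0.5 else "-"
                    inst = _instantiate(by_name[el].consensus, rng)
                    if strand == "-":
                        inst = reverse_complement(inst)
                    seq[pos : pos + k] = list(inst)
                    taken.append((pos, pos + k))
                    placements.append({"element": el, "strand": strand, "start": pos + 1})
                if not ok:
                    break
            if not ok:
                continue
            realized = scan_elements(gene, "".join(seq), catalog)
            counts = {e.name: 0 for e in catalog}
            for o in realized:
                counts[o.element] += 1
            if counts == want_total:
                promoters.append((gene, "".join(seq)))
                placed_record = placements
                break
        if placed_record is None:
            raise ValidationError(
                f"{gene}: could not realize exact planted counts (conflicting catalog?)"
            )
        entries[gene] = {"plants": placed_record, "counts": {k: v for k, v in want_total.items() if v}}
    return promoters, TruthManifest("promoters", seed, entries)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int,
    groups: Mapping[str, int],
    effects: np.ndarray | None = None,
    cq_fold_changes: Mapping[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    replicates: int = 3,
) -> tuple[pd.DataFrame, Mapping[str, str], pd.DataFrame | None, TruthManifest]:
    """Expression matrix plus (optionally) a Cq table with planted fold changes.

    ``groups`` maps group/tissue name to its sample count. The matrix is
    ``group_mean × gene_effect`` with multiplicative lognormal noise
    (sigma = ``noise_sd``); ``effects`` may be a ``(n_genes,)`` vector or a
    ``(n_genes, n_groups)`` array (planted cluster structure). Cq tables get
    ``replicates`` control and treated replicates per gene with ΔΔCt =
    −log2(fold change) plus Gaussian cycle noise of the same sigma.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    group_names = list(groups)
    group_means = {g: 1000.0 * (i + 1) for i, g in enumerate(group_names)}
    if effects is None:
        effects_arr = rng.lognormal(0.0, 0.5, size=(n_genes, len(group_names)))
    else:
        effects_arr = np.asarray(effects, dtype=float)
        if effects_arr.ndim == 1:
            effects_arr = np.repeat(effects_arr[:, None], len(group_names), axis=1)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    cols: list[str] = []
    grouping: dict[str, str] = {}
    data = []
    for gi, g in enumerate(group_names):
        for s in range(groups[g]):
            col = f"{g}_s{s + 1}"
            cols.append(col)
            grouping[col] = g
            noise = (
                rng.lognormal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else np.ones(n_genes)
            )
            data.append(group_means[g] * effects_arr[:, gi] * noise)
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)

    cq = None
    cq_truth = {}
    if cq_fold_changes:
        rows = []
        for gene, fold in cq_fold_changes.items():
            base_dct = float(rng.uniform(1.0, 5.0))
            for cond, dct in (("control", base_dct), ("treated", base_dct - np.log2(fold))):
                for r in range(replicates):
                    ref = 20.0 + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                    tgt = ref + dct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "gene": gene,
                            "condition": cond,
                            "replicate": r + 1,
                            "cq_target": tgt,
                            "cq_reference": ref,
                        }
                    )
            cq_truth[gene] = float(fold)
        cq = pd.DataFrame(rows)

    manifest = TruthManifest(
        "expression",
        seed,
        {
            "group_means": group_means,
            "noise_sd": float(noise_sd),
            "cq_fold_changes": cq_truth,
            "n_genes": int(n_genes),
        },
    )
    return matrix, grouping, cq, manifest
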