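"""Two-species copy-number evolution: orthogroups, MRCA counts, gains/losses.

For one gene family observed in two species, cross-species ortholog clusters
stand in for the ancestral genes: the ancestral (MRCA) copy number is the
number of clusters, a lineage *loses* a gene for every cluster in which it is
absent, and *gains* are the extant surplus over the clusters it occupies, so
that ``extant = ancestral - losses + gains`` holds by construction.

Clustering is reciprocal-best-hit seeding followed by best-hit attachment of
the remaining genes (an identity threshold gates attachment; unattached genes
become singletons). A small neighbor-joining utility is provided for building
family trees from distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import ValidationError, load_bundled_table

__all__ = [
    "OrthoGroupSet",
    "ExpansionSummary",
    "build_orthogroups",
    "mrca_counts",
    "gains_losses",
    "nj_tree",
    "load_fig4_scenarios",
]


@dataclass(frozen=True)
class OrthoGroupSet:
    """Disjoint clusters of genes from two species (tagged "A"/"B")."""

    family: int
    clusters: tuple[frozenset[tuple[str, str]], ...]  # members are (species, gene_id)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for cl in self.clusters:
            if not cl:
                raise ValidationError("empty orthogroup cluster")
            if seen & cl:
                raise ValidationError("orthogroup clusters are not disjoint")
            seen |= cl

    def extant(self, species: str) -> int:
        return sum(1 for cl in self.clusters for sp, _ in cl if sp == species)

    def occupied(self, species: str) -> int:
        """Clusters containing at least one gene of *species*."""
        return sum(1 for cl in self.clusters if any(sp == species for sp, _ in cl))


@dataclass(frozen=True)
class ExpansionSummary:
    family: int
    ancestral_count: int
    extant_a: int
    extant_b: int
    gains_a: int
    gains_b: int
    losses_a: int
    losses_b: int

    def __post_init__(self) -> None:
        for sp, extant, gains, losses in (
            ("A", self.extant_a, self.gains_a, self.losses_a),
            ("B", self.extant_b, self.gains_b, self.losses_b),
        ):
            if min(gains, losses) < 0:
                raise ValidationError(f"species {sp}: negative gains/losses")
            if extant != self.ancestral_count - losses + gains:
                raise ValidationError(
                    f"species {sp}: extant != ancestral - losses + gains"
                )


def build_orthogroups(
    genes_a: Mapping[str, str],
    genes_b: Mapping[str, str],
    identity_fn: Callable[[str, str], float],
    threshold: float,
    family: int = 0,
) -> OrthoGroupSet:
    """Cluster two species' gene sets by reciprocal best hits.

    ``genes_a``/``genes_b`` map gene IDs to protein sequences. Reciprocal
    best hits across species seed clusters; every remaining gene joins the
    cluster of its best cross-species hit when that identity reaches
    *threshold*, else it forms a singleton. Deterministic for a fixed input
    order (dict order; ties broken by gene ID).
    """
    if not genes_a and not genes_b:
        raise ValidationError("both species have no genes")
    ids_a, ids_b = sorted(genes_a), sorted(genes_b)
    ident: dict[tuple[str, str], float] = {
        (ga, gb): identity_fn(genes_a[ga], genes_b[gb]) for ga in ids_a for gb in ids_b
    }

    def best_hit(g: str, own: str) -> str | None:
        if own == "A":
            cands = [(ident[(g, gb)], gb) for gb in ids_b]
        else:
            cands = [(ident[(ga, g)], ga) for ga in ids_a]
        if not cands:
            return None
        return max(cands, key=lambda t: (t[0], _rev(t[1])))[1]

    best_a = {g: best_hit(g, "A") for g in ids_a}
    best_b = {g: best_hit(g, "B") for g in ids_b}

    clusters: list[set[tuple[str, str]]] = []
    member_of: dict[tuple[str, str], int] = {}
    for ga in ids_a:
        gb = best_a[ga]
        if gb is not None and best_b[gb] == ga:
            clusters.append({("A", ga), ("B", gb)})
            member_of[("A", ga)] = member_of[("B", gb)] = len(clusters) - 1

    for sp, ids, bests, key in (("A", ids_a, best_a, 0), ("B", ids_b, best_b, 1)):
        for g in ids:
            if (sp, g) in member_of:
                continue
            hit = bests[g]
            pair = (g, hit) if sp == "A" else (hit, g)
            other = ("B" if sp == "A" else "A", hit)
            if hit is not None and ident[pair] >= threshold and other in member_of:
                ci = member_of[other]
                clusters[ci].add((sp, g))
                member_of[(sp, g)] = ci
            else:
                clusters.append({(sp, g)})
                member_of[(sp, g)] = len(clusters) - 1

    return OrthoGroupSet(family, tuple(frozenset(c) for c in clusters))


class _rev(str):
    def __lt__(self, other):  # max() prefers lexicographically smaller ID on ties
        return str.__gt__(self, other)


def mrca_counts(ortho: OrthoGroupSet) -> int:
    """Ancestral (MRCA) copy number = number of ortholog clusters."""
    return len(ortho.clusters)


def gains_losses(
    ortho: OrthoGroupSet, extant_counts: tuple[int, int] | None = None
) -> ExpansionSummary:
    """Per-lineage gene gains and losses relative to the MRCA.

    ``losses_X`` counts clusters with no species-X member; ``gains_X`` is the
    extant surplus of species X over the clusters it occupies.
    """
    anc = mrca_counts(ortho)
    extant_a, extant_b = ortho.extant("A"), ortho.extant("B")
    if extant_counts is not None and extant_counts != (extant_a, extant_b):
        raise ValidationError(
            f"supplied extant counts {extant_counts} != cluster totals "
            f"({extant_a}, {extant_b})"
        )
    occ_a, occ_b = ortho.occupied("A"), ortho.occupied("B")
    return ExpansionSummary(
        family=ortho.family,
        ancestral_count=anc,
        extant_a=extant_a,
        extant_b=extant_b,
        gains_a=extant_a - occ_a,
        gains_b=extant_b - occ_b,
        losses_a=anc - occ_a,
        losses_b=anc - occ_b,
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree (Newick, unrooted) from a distance matrix.

    Standard Saitou–Nei agglomeration with the canonical Q criterion;
    tied minimal Q values join the lexicographically smallest index pair.
    Negative branch-length estimates are clamped to 0.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValidationError("distance matrix and labels are inconsistent")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValidationError("distances must be non-negative with a zero diagonal")
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    nodes = [str(l) for l in labels]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    newick: dict[int, str] = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * dist[(i, j)] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dij)
            dist[(u, k)] = dist[(k, u)] = max(duk, 0.0)
        dist[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-taxon closed form for the central node's branch lengths
    li = 0.5 * (dist[(i, j)] + dist[(i, k)] - dist[(j, k)])
    lj = 0.5 * (dist[(i, j)] + dist[(j, k)] - dist[(i, k)])
    lk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dist[(i, j)])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    return f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"


def load_fig4_scenarios() -> dict[str, OrthoGroupSet]:
    """Bundled two-species cluster scenarios with printed copy-number truths.

    Each scenario encodes one family's ortholog clusters as per-cluster
    species counts; synthetic member IDs are generated so the structures can
    flow through :func:`gains_losses` unchanged.
    """
    df = load_bundled_table("fig4_scenarios.tsv")
    out: dict[str, OrthoGroupSet] = {}
    for name, sub in df.groupby("scenario", sort=False):
        clusters = []
        family = int(sub["family"].iloc[0])
        for row in sub.itertuples(index=False):
            members = {("A", f"{name}.c{row.cluster}.a{i}") for i in range(int(row.n_a))}
            members |= {("B", f"{name}.c{row.cluster}.b{i}") for i in range(int(row.n_b))}
            clusters.append(frozenset(members))
        out[str(name)] = OrthoGroupSet(family, tuple(clusters))
    return out
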