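"""Expression-matrix summaries and qPCR relative quantification.

Microarray/RNA-seq style matrices (genes × samples, non-negative values) are
summarized as percent-of-row-maximum "expression potential" levels, per
condition/tissue averages, and counts of genes exceeding a high-expression
threshold (default 60% of the row maximum). Rows are ordered for heatmaps by
agglomerative clustering with Manhattan (city-block) distance and average
linkage.

qPCR fold changes use the 2^-ΔΔCt method: per condition ΔCt = Cq(target) -
Cq(reference); ΔΔCt of each treated replicate is taken against the mean
control ΔCt; fold change is reported as mean ± standard error of the
per-replicate 2^-ΔΔCt values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .core_model import ValidationError

__all__ = [
    "validate_matrix",
    "percent_of_max",
    "condition_average",
    "high_expression_count",
    "hcluster_rows",
    "ddct_fold_change",
    "CQ_COLUMNS",
]

#: Required columns of a Cq table.
CQ_COLUMNS = ["gene", "condition", "replicate", "cq_target", "cq_reference"]


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.hasnans or matrix.columns.hasnans:
        raise ValidationError("matrix has missing row/column labels")
    if (matrix.values < 0).any():
        raise ValidationError("expression values must be non-negative")


def percent_of_max(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each gene row to percent of its maximum.

    Returns the percent matrix and the list of all-zero genes, which cannot
    be assessed (their rows are NaN in the output).
    """
    validate_matrix(matrix)
    row_max = matrix.max(axis=1)
    flagged = list(matrix.index[row_max == 0])
    pct = matrix.div(row_max.replace(0, np.nan), axis=0) * 100.0
    return pct, flagged


def condition_average(matrix: pd.DataFrame, grouping: Mapping[str, str]) -> pd.Series:
    """Mean over all gene × sample cells per sample group.

    *grouping* maps every sample (column) to a group label; each column must
    be assigned to exactly one group.
    """
    validate_matrix(matrix)
    missing = [c for c in matrix.columns if c not in grouping]
    if missing:
        raise ValidationError(f"samples without a group: {missing}")
    groups = sorted(set(grouping.values()))
    out = {}
    for g in groups:
        cols = [c for c in matrix.columns if grouping[c] == g]
        if not cols:
            raise ValidationError(f"group {g!r} has no samples")
        out[g] = float(matrix[cols].values.mean())
    return pd.Series(out, name="mean_expression")


def high_expression_count(
    percent_matrix: pd.DataFrame,
    tissue_grouping: Mapping[str, str],
    threshold: float = 60.0,
) -> pd.Series:
    """Per tissue, the number of genes whose percent level exceeds *threshold*.

    A gene counts for a tissue when any of the tissue's samples exceeds the
    threshold in that gene's percent-of-max row.
    """
    tissues = sorted(set(tissue_grouping.values()))
    counts = {}
    for t in tissues:
        cols = [c for c in percent_matrix.columns if tissue_grouping.get(c) == t]
        if not cols:
            counts[t] = 0
            continue
        counts[t] = int(((percent_matrix[cols] > threshold).any(axis=1)).sum())
    return pd.Series(counts, name="n_high_expression", dtype=int)


def hcluster_rows(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Order gene rows by Manhattan-distance average-linkage clustering.

    Returns the SciPy linkage matrix and the leaf order as row labels.
    Rows must share a common length (guaranteed by the DataFrame); fewer
    than two rows is an error.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    if matrix.isna().any().any():
        raise ValidationError("matrix contains missing values")
    dist = pdist(matrix.values, metric="cityblock")
    link = average(dist)
    order = [matrix.index[i] for i in leaves_list(link)]
    return link, order


def ddct_fold_change(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene 2^-ΔΔCt fold change, mean ± standard error over replicates.

    The table needs columns ``gene, condition, replicate, cq_target,
    cq_reference`` with conditions ``control`` and ``treated``. ΔΔCt of each
    treated replicate is its ΔCt minus the mean control ΔCt; SE is computed
    on the per-replicate fold changes (ddof=1; 0 for a single replicate).
    """
    missing = [c for c in CQ_COLUMNS if c not in cq_table.columns]
    if missing:
        raise ValidationError(f"Cq table missing columns: {missing}")
    if cq_table[["cq_target", "cq_reference"]].isna().any().any():
        raise ValidationError("missing Cq value (target or reference)")
    if (cq_table[["cq_target", "cq_reference"]].values <= 0).any():
        raise ValidationError("Cq values must be positive")

    rows = []
    for gene, sub in cq_table.groupby("gene", sort=False):
        ctrl = sub[sub["condition"] == "control"]
        trt = sub[sub["condition"] == "treated"]
        if ctrl.empty or trt.empty:
            raise ValidationError(f"{gene}: need control and treated replicates")
        dct_ctrl = (ctrl["cq_target"] - ctrl["cq_reference"]).mean()
        ddct = (trt["cq_target"] - trt["cq_reference"]) - dct_ctrl
        fold = np.power(2.0, -ddct)
        mean = float(fold.mean())
        se = float(fold.std(ddof=1) / math.sqrt(len(fold))) if len(fold) > 1 else 0.0
        rows.append(
            {"gene": gene, "fold_change": mean, "se": se, "n_replicates": len(fold)}
        )
    return pd.DataFrame(rows)
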