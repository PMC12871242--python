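"""Inside- vs. outside-niche differential expression for one cell type.

Counts are library-size normalised (each cell scaled to ``target_sum`` total,
then log1p), and each gene is contrasted between niche-member and
non-member cells of the chosen type with a two-sided Wilcoxon rank-sum test
(normal approximation with tie correction and continuity correction) —
the field-standard nonparametric contrast for targeted-panel counts.
P-values are Benjamini-Hochberg adjusted across the tested genes only
(genes detected in neither group are excluded first and reported); adjusting
over the pre-filter set would inflate every q deterministically.

The log2 fold change is log2((mean_in + pc) / (mean_out + pc)) on the
normalised values, with a tiny pseudocount (default 1e-9) that avoids
infinite ratios without perturbing ranks; the pseudocount never enters the
test itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError
from .types import CellTable, CellType, CountMatrix

NO_NICHE = "NONE"


@dataclass
class NormalizedCounts:
    """Library-size-normalised, log1p-transformed expression (genes x cells)."""

    genes: list[str]
    cells: list[str]
    X: sp.csr_matrix  # float
    n_dropped_cells: int
    dropped_cell_ids: list[str]


def normalize_counts(
    counts: CountMatrix, target_sum: float = 10_000.0
) -> NormalizedCounts:
    """Scale every cell to ``target_sum`` total counts, then log1p.

    Cells with zero total count cannot be normalised; they are dropped and
    reported.  Per-cell sums of expm1(normalised) equal target_sum exactly
    (up to float rounding).
    """
    totals = np.asarray(counts.X.sum(axis=0)).ravel()
    if (totals == 0).all():
        raise DomainError("all-zero count matrix cannot be normalised")
    keep = totals > 0
    dropped = [c for c, k in zip(counts.cells, keep) if not k]
    X = sp.csc_matrix(counts.X, dtype=float)[:, keep]
    scale = target_sum / totals[keep]
    X = X @ sp.diags(scale)
    X.data = np.log1p(X.data)
    return NormalizedCounts(
        genes=list(counts.genes),
        cells=[c for c, k in zip(counts.cells, keep) if k],
        X=sp.csr_matrix(X),
        n_dropped_cells=len(dropped),
        dropped_cell_ids=dropped,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene inside-vs-outside contrast table plus filter bookkeeping."""

    table: pd.DataFrame  # gene, n_inside, n_outside, log2_fold_change, p_value, q_value
    n_inside: int
    n_outside: int
    n_genes_filtered: int  # genes detected in neither group, excluded pre-test


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:  # all values tied: no evidence
        return 1.0
    return float(
        mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def de_inside_outside(
    cells: CellTable,
    counts: CountMatrix,
    membership: Mapping[str, str] | pd.Series,
    cell_type: CellType | str,
    min_cells_per_group: int = 10,
    pseudocount: float = 1e-9,
    target_sum: float = 10_000.0,
    alpha: float = 0.05,
) -> DEResult:
    """Contrast expression of one cell type inside vs. outside microniches.

    ``membership`` maps cell_id to a niche id or NONE (from
    :func:`clonalniche.spatial.assign_niche_membership`).  Requires at least
    ``min_cells_per_group`` cells of ``cell_type`` on each side — below that
    the rank-sum normal approximation is unreliable.  Output is sorted by q
    ascending, ties by \\|log2FC\\| descending, then gene name.
    """
    cell_type = CellType(cell_type)
    membership = pd.Series(dict(membership)) if not isinstance(
        membership, pd.Series
    ) else membership

    norm = normalize_counts(counts, target_sum=target_sum)
    col = {c: j for j, c in enumerate(norm.cells)}

    typed = cells.df[cells.df["cell_type"] == cell_type.value]["cell_id"]
    typed = [c for c in typed if c in col]  # zero-total cells were dropped
    inside = [c for c in typed if membership.get(c, NO_NICHE) != NO_NICHE]
    outside = [c for c in typed if membership.get(c, NO_NICHE) == NO_NICHE]
    if len(inside) < min_cells_per_group:
        raise DomainError(
            f"inside group has {len(inside)} {cell_type.value} cells "
            f"(< {min_cells_per_group})"
        )
    if len(outside) < min_cells_per_group:
        raise DomainError(
            f"outside group has {len(outside)} {cell_type.value} cells "
            f"(< {min_cells_per_group})"
        )

    Xi = norm.X[:, [col[c] for c in inside]].toarray()
    Xo = norm.X[:, [col[c] for c in outside]].toarray()
    raw = sp.csr_matrix(counts.X)
    raw_cols = {c: j for j, c in enumerate(counts.cells)}
    Ri = raw[:, [raw_cols[c] for c in inside]]
    Ro = raw[:, [raw_cols[c] for c in outside]]
    detected = (
        np.asarray(Ri.sum(axis=1)).ravel() + np.asarray(Ro.sum(axis=1)).ravel()
    ) > 0
    n_filtered = int((~detected).sum())

    genes = [g for g, d in zip(norm.genes, detected) if d]
    idx = np.flatnonzero(detected)
    log2fc = np.log2(
        (Xi[idx].mean(axis=1) + pseudocount) / (Xo[idx].mean(axis=1) + pseudocount)
    )
    pvals = np.array([_ranksum_p(Xi[i], Xo[i]) for i in idx])
    qvals = bh_adjust(pvals)

    table = pd.DataFrame(
        {
            "gene": genes,
            "n_inside": len(inside),
            "n_outside": len(outside),
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    table["_absfc"] = table["log2_fold_change"].abs()
    table = (
        table.sort_values(
            ["q_value", "_absfc", "gene"], ascending=[True, False, True]
        )
        .drop(columns="_absfc")
        .reset_index(drop=True)
    )
    return DEResult(
        table=table,
        n_inside=len(inside),
        n_outside=len(outside),
        n_genes_filtered=n_filtered,
    )


def write_de_table(result: DEResult, path) -> None:
    """Write a DE table as TSV with stable column order and 6-digit floats."""
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
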