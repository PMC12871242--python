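"""Clonal-architecture statistics per subject.

The central quantity is the R20 score: rank clones by descending size and
return the fraction of unique clones needed to account for 20% of all
sequenced cells.  Low R20 means few clones dominate the repertoire
(oligoclonal expansion); R20 for a fully polyclonal repertoire of C singleton
clones is ceil(0.2*C)/C.  A clone is "expanded" when more than one cell
carries the same clonotype, and "shared" when it contains both Foxp3+ (Treg)
and Foxp3- (Tconv) cells — the signature of peripheral Treg induction from a
common naive precursor.

Repertoire mass is counted in cells (one cell = one unit).  The cumulative
threshold comparison is inclusive (cumulative count >= 0.2 * N); strict
inequality would change the answer on exact-boundary repertoires.  Statistics
are always per subject; cross-subject testing is left to the caller.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .types import CloneCategory, CloneRecord, RepertoireSummary, RepertoireTable


def summarize_clones(rep: RepertoireTable, subject_id: str) -> list[CloneRecord]:
    """One CloneRecord per distinct clone among a subject's cells.

    Counts partition the subject's cells exactly.  Records are returned in
    ascending clone_id order for reproducibility.
    """
    sub = rep.df[rep.df["subject_id"] == subject_id]
    if sub.empty:
        raise DomainError(f"unknown subject_id '{subject_id}'")
    records = []
    grouped = sub.groupby("clone_id", sort=True)["lineage"]
    for clone_id, lineages in grouped:
        n_treg = int((lineages == "TREG").sum())
        n_tconv = int((lineages == "TCONV").sum())
        records.append(
            CloneRecord(
                clone_id=str(clone_id),
                size=n_treg + n_tconv,
                n_treg=n_treg,
                n_tconv=n_tconv,
                category=CloneRecord.categorize(n_treg, n_tconv),
            )
        )
    return records


def r20_score(
    clone_sizes: Sequence[int], fraction_threshold: float = 0.20
) -> float:
    """Fraction of unique clones (largest first) accounting for 20% of cells.

    Sort clones by size descending; with N total cells, find the smallest k
    such that the top-k cumulative cell count >= fraction_threshold * N
    (inclusive), and return k / C where C is the number of unique clones.
    Ties in size affect which clones are in the top k, never k itself, so the
    score is deterministic.  A monoclonal repertoire returns 1.0 (1 clone out
    of 1); callers should treat that value as degenerate, not polyclonal.
    """
    sizes = np.asarray(list(clone_sizes))
    if sizes.size == 0:
        raise DomainError("r20 undefined on an empty clone list")
    if (sizes < 1).any():
        raise ValidationError("clone sizes must be >= 1")
    ordered = np.sort(sizes)[::-1]
    n_cells = int(ordered.sum())
    # exact rational threshold: 0.2 * 15 in binary floats exceeds 3 and would
    # misplace the inclusive boundary, so compare cum * denom >= num instead
    thr = Fraction(str(fraction_threshold)) * n_cells
    cumulative = np.cumsum(ordered)
    k = int(np.argmax(cumulative * thr.denominator >= thr.numerator)) + 1
    return k / sizes.size


def expanded_fraction(clones: Sequence[CloneRecord]) -> float:
    """Fraction of clones with more than one cell."""
    if not clones:
        raise DomainError("expanded fraction undefined on an empty clone list")
    return sum(c.expanded for c in clones) / len(clones)


def expanded_composition(
    clones: Sequence[CloneRecord],
) -> dict[CloneCategory, float]:
    """Category fractions among expanded clones (sum to 1).

    Returns an empty mapping when no clone is expanded — a valid outcome for
    fully polyclonal repertoires, not an error.
    """
    expanded = [c for c in clones if c.expanded]
    if not expanded:
        return {}
    n = len(expanded)
    return {
        cat: sum(c.category == cat for c in expanded) / n for cat in CloneCategory
    }


def summarize_subject(rep: RepertoireTable, subject_id: str) -> RepertoireSummary:
    """Assemble the per-subject clonal summary."""
    clones = summarize_clones(rep, subject_id)
    sizes = [c.size for c in clones]
    return RepertoireSummary(
        subject_id=subject_id,
        n_cells=sum(sizes),
        n_clones=len(clones),
        r20=r20_score(sizes),
        expanded_fraction=expanded_fraction(clones),
        expanded_category_fractions=expanded_composition(clones),
        shared_clone_count=sum(c.category == CloneCategory.SHARED for c in clones),
        monoclonal=len(clones) == 1,
    )


def subsample_statistic(
    rep: RepertoireTable,
    subject_id: str,
    statistic: str,
    n_cells_target: int,
    n_boot: int = 200,
    seed: Optional[int] = None,
) -> tuple[float, tuple[float, float]]:
    """Subsampled mean and 2.5/97.5 percentile interval of a clonality statistic.

    Repeatedly draws ``n_cells_target`` cells without replacement from the
    subject and recomputes the statistic ("R20" or "EXPANDED_FRACTION").
    Normalises unequal cell counts per subject before cross-subject
    comparison.  Reproducible given ``seed``.
    """
    if statistic not in ("R20", "EXPANDED_FRACTION"):
        raise ValidationError(f"unknown statistic '{statistic}'")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    sub = rep.df[rep.df["subject_id"] == subject_id]
    if sub.empty:
        raise DomainError(f"unknown subject_id '{subject_id}'")
    if n_cells_target > len(sub):
        raise DomainError(
            f"n_cells_target {n_cells_target} exceeds subject cell count {len(sub)}"
        )
    rng = np.random.default_rng(seed)
    clone_ids = sub["clone_id"].to_numpy()
    lineages = sub["lineage"].to_numpy()
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(len(sub), size=n_cells_target, replace=False)
        frame = pd.DataFrame({"clone_id": clone_ids[idx], "lineage": lineages[idx]})
        sizes = frame.groupby("clone_id").size()
        if statistic == "R20":
            values[b] = r20_score(sizes.to_numpy())
        else:
            values[b] = (sizes > 1).sum() / len(sizes)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def uniform_r20(n_clones: int, fraction_threshold: float = 0.20) -> float:
    """Closed form for C equal-sized clones: ceil(0.2*C)/C."""
    return math.ceil(Fraction(str(fraction_threshold)) * n_clones) / n_clones


def summaries_frame(rep: RepertoireTable) -> pd.DataFrame:
    """One RepertoireSummary row per subject, as a flat DataFrame."""
    rows = []
    for subject in rep.subjects():
        s = summarize_subject(rep, subject)
        comp = s.expanded_category_fractions
        rows.append(
            {
                "subject_id": s.subject_id,
                "n_cells": s.n_cells,
                "n_clones": s.n_clones,
                "r20": s.r20,
                "expanded_fraction": s.expanded_fraction,
                "frac_expanded_treg_only": comp.get(CloneCategory.TREG_ONLY, np.nan),
                "frac_expanded_tconv_only": comp.get(CloneCategory.TCONV_ONLY, np.nan),
                "frac_expanded_shared": comp.get(CloneCategory.SHARED, np.nan),
                "shared_clone_count": s.shared_clone_count,
                "monoclonal": s.monoclonal,
            }
        )
    return pd.DataFrame(rows)
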