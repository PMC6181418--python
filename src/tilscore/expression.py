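"""Two-group differential expression with BH false-discovery control.

Emulates the luminal-vs-basal comparison of T-cell cytotoxicity gene
expression: per gene, a two-sided Welch (unequal-variance) t-test on
log-scale values between the two subtype groups, Benjamini-Hochberg
adjustment across all tested genes, and a gene-set summary of how many
cytotoxicity-set members are significant and in which direction. Mean
differences are signed basal − luminal throughout.

The exact test behind the original comparison is not pinned down beyond
"evaluated in R/Bioconductor"; the Welch test on log-scale values is a
method-agnostic, fully specified choice that is defensible on normalized
expression data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["DEResult", "GeneSetSummary", "de_two_group", "bh_adjust",
           "geneset_summary", "de_records"]

SUBTYPES = ("luminal", "basal")


@dataclass(frozen=True)
class DEResult:
    """Per-gene two-group result row (basal − luminal)."""

    gene_id: str
    mean_diff: float
    statistic: float
    p: float
    q: float
    in_cytotoxicity_set: bool


def de_records(results: pd.DataFrame) -> list["DEResult"]:
    """View a :func:`de_two_group` frame as typed per-gene records."""
    return [DEResult(gene_id=str(g), **row)
            for g, row in results.iterrows()]


@dataclass(frozen=True)
class GeneSetSummary:
    n_set: int
    n_tested: int
    n_significant: int
    n_up_in_basal: int
    n_down_in_basal: int
    fraction_significant: float
    threshold: float
    missing_ids: list[str] = field(default_factory=list)


def _split_groups(matrix: pd.DataFrame, labels: pd.DataFrame):
    if matrix.index.duplicated().any():
        raise DataError("duplicate gene IDs in expression matrix")
    if matrix.columns.duplicated().any():
        raise DataError("duplicate sample IDs in expression matrix")
    lab = labels.set_index("sample_id")["subtype"]
    unlabeled = [s for s in matrix.columns if s not in lab.index]
    if unlabeled:
        raise DataError(f"unlabeled samples: {unlabeled[:5]}")
    bad = set(lab.unique()) - set(SUBTYPES)
    if bad:
        raise DataError(f"unknown subtype labels: {sorted(bad)}")
    lum = [s for s in matrix.columns if lab[s] == "luminal"]
    bas = [s for s in matrix.columns if lab[s] == "basal"]
    if len(lum) < 2 or len(bas) < 2:
        raise DataError("each subtype needs at least two samples")
    return matrix[lum].to_numpy(dtype=float), matrix[bas].to_numpy(dtype=float)


def de_two_group(
    matrix: pd.DataFrame,
    labels: pd.DataFrame,
    gene_set: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-gene Welch t-test between basal and luminal samples.

    Returns a DataFrame indexed like ``matrix`` with columns mean_diff
    (basal − luminal, log units), statistic, p, q (BH across all genes) and
    in_cytotoxicity_set. Genes with zero variance in both groups get p = 1
    with a warning.
    """
    if matrix.shape[0] < 1:
        raise DataError("expression matrix has no genes")
    lum, bas = _split_groups(matrix, labels)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(bas, lum, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(stat)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both "
            "groups; p set to 1", stacklevel=2)
        stat[degenerate] = 0.0
        p[degenerate] = 1.0
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    members = set(gene_set)
    return pd.DataFrame({
        "mean_diff": bas.mean(axis=1) - lum.mean(axis=1),
        "statistic": stat,
        "p": p,
        "q": bh_adjust(p),
        "in_cytotoxicity_set": [g in members for g in matrix.index],
    }, index=matrix.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def geneset_summary(
    results: pd.DataFrame,
    gene_set: Sequence[str],
    threshold: float = 0.05,
) -> tuple[GeneSetSummary, pd.Index]:
    """Significance summary for a gene set, split by direction.

    Counts set members with q < ``threshold``, split by the sign of the
    basal − luminal mean difference. Set IDs absent from the results are
    reported in ``missing_ids`` (not fatal). Also returns the index of set
    members present, ordered by ascending q — the row slice to export for a
    heatmap.
    """
    ids = list(gene_set)
    if len(ids) == 0:
        raise DataError("empty gene set")
    present = [g for g in ids if g in results.index]
    missing = [g for g in ids if g not in results.index]
    if not present:
        raise DataError("no gene-set member appears in the results")
    sub = results.loc[present]
    sig = sub["q"] < threshold
    up = sig & (sub["mean_diff"] > 0)
    down = sig & (sub["mean_diff"] < 0)
    order = sub.sort_values("q").index
    summary = GeneSetSummary(
        n_set=len(ids),
        n_tested=len(present),
        n_significant=int(sig.sum()),
        n_up_in_basal=int(up.sum()),
        n_down_in_basal=int(down.sum()),
        fraction_significant=float(sig.mean()),
        threshold=threshold,
        missing_ids=missing,
    )
    return summary, order
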