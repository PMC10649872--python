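"""Targeted single-cell qPCR: LOD normalization, signature scores, cell typing.

Normalization maps each detected reaction to log2 expression as
``LOD - Ct`` floored at 0; not-detected reactions are 0.  Signatures are
scored as the average per-gene Z-score computed over *all* cells — the
reference population is fixed before any classification, so removing
excluded cells afterwards never changes a score.

Cell-type rules (checked in order, strict inequalities):

1. Schwannian score > 0.75                          -> schwannian
2. neuroblast > 0 and neuroblast > ganglion          -> neuroblast
3. ganglion  > 0 and ganglion  > neuroblast          -> ganglion
4. otherwise (including exact neuroblast/ganglion ties) -> excluded
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtMatrix, ExpressionMatrix, GeneSignature

__all__ = [
    "CellClassification",
    "normalize_ct",
    "signature_score",
    "score_signatures",
    "classify_cells",
    "rank_sum_test",
    "compare_groups",
    "marker_correlation",
]

SCHWANNIAN_THRESHOLD = 0.75
EXCLUDED = "excluded"


@dataclass
class CellClassification:
    """Per-cell marker-signature scores plus the assigned label."""

    scores: pd.DataFrame  # columns: neuroblast, ganglion, schwannian
    labels: pd.Series  # one of neuroblast/ganglion/schwannian/excluded

    def kept(self) -> pd.Index:
        return self.labels.index[self.labels != EXCLUDED]


def normalize_ct(ct: CtMatrix) -> ExpressionMatrix:
    """log2 expression = LOD - Ct (floored at 0); not-detected -> 0."""
    expr = (ct.lod - ct.ct).clip(lower=0.0)
    expr = expr.where(ct.detected, 0.0)
    return ExpressionMatrix(expr.astype(float), meta=ct.meta)


def _zscores(expr: ExpressionMatrix, sig: GeneSignature) -> pd.DataFrame:
    present = [g for g in sig.genes if g in expr.data.columns]
    absent = [g for g in sig.genes if g not in expr.data.columns]
    if absent:
        warnings.warn(
            f"signature {sig.name!r}: genes absent from matrix, dropped: {absent}",
            stacklevel=3,
        )
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    sub = expr.data[present]
    sd = sub.std(axis=0, ddof=1)
    flat = sd[~(sd > 0)].index.tolist()
    if flat:
        warnings.warn(
            f"signature {sig.name!r}: zero-variance genes dropped from Z-scoring: {flat}",
            stacklevel=3,
        )
        present = [g for g in present if g not in flat]
        if not present:
            # all-flat signature carries no information: score 0 everywhere
            return pd.DataFrame(0.0, index=expr.data.index, columns=list(sig.genes)[:1])
        sub = expr.data[present]
        sd = sub.std(axis=0, ddof=1)
    return (sub - sub.mean(axis=0)) / sd


def signature_score(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Average per-gene Z over signature genes, one value per cell/sample."""
    z = _zscores(expr, sig)
    score = z.mean(axis=1)
    score.name = sig.name
    return score


def score_signatures(
    expr: ExpressionMatrix, signatures: dict[str, GeneSignature]
) -> pd.DataFrame:
    """Score several signatures at once; columns follow the dict order."""
    return pd.DataFrame({name: signature_score(expr, s) for name, s in signatures.items()})


def classify_cells(scores: pd.DataFrame) -> CellClassification:
    """Apply the threshold rules to per-cell marker-signature scores.

    ``scores`` needs columns ``neuroblast``, ``ganglion``, ``schwannian``.
    The Schwannian rule takes precedence; cells satisfying no rule
    (including exact neuroblast/ganglion ties) are excluded.
    """
    for col in ("neuroblast", "ganglion", "schwannian"):
        if col not in scores.columns:
            raise ValueError(f"missing score column {col!r}")
        if scores[col].isna().any():
            raise ValueError(f"missing values in score column {col!r}")
    n, g, s = scores["neuroblast"], scores["ganglion"], scores["schwannian"]
    labels = pd.Series(EXCLUDED, index=scores.index, dtype=object)
    labels[(g > 0) & (g > n)] = "ganglion"
    labels[(n > 0) & (n > g)] = "neuroblast"
    labels[s > SCHWANNIAN_THRESHOLD] = "schwannian"
    labels.name = "cell_type"
    return CellClassification(scores=scores.copy(), labels=labels)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the pooled sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U statistic of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    values: pd.Series, groups: pd.Series, group_a: str, group_b: str
) -> dict:
    """Rank-sum comparison of a per-cell score between two labelled groups."""
    a = values[groups == group_a]
    b = values[groups == group_b]
    if a.empty or b.empty:
        raise ValueError(f"empty group in comparison {group_a!r} vs {group_b!r}")
    stat, p = rank_sum_test(a.to_numpy(), b.to_numpy())
    return {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "statistic": stat,
        "p_value": p,
    }


def marker_correlation(
    expr: ExpressionMatrix, sig_scores: pd.Series, marker_gene: str
) -> dict:
    """Pearson correlation between a signature score and one marker gene."""
    if marker_gene not in expr.data.columns:
        raise ValueError(f"marker gene {marker_gene!r} not in matrix")
    marker = expr.data[marker_gene].reindex(sig_scores.index)
    mask = np.isfinite(marker.to_numpy()) & np.isfinite(sig_scores.to_numpy())
    if mask.sum() < 3:
        raise ValueError("need at least 3 cells with finite values")
    m = marker.to_numpy()[mask]
    s = sig_scores.to_numpy()[mask]
    if np.std(m) == 0 or np.std(s) == 0:
        raise ValueError("zero variance in marker or score vector")
    r, p = stats.pearsonr(s, m)
    return {"pearson_r": float(r), "p_value": float(p), "n": int(mask.sum())}
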