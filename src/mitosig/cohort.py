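"""Tumor-cohort stratification by the divergence gene panel and survival.

Tumors are clustered (Ward criterion on per-gene-standardized expression of
the panel genes) into three strata which are then named MGS.High, MGS.Int
and MGS.Low by descending mean mitotic-gene-signature score.  Strata are
related to overall survival with the Kaplan-Meier product-limit estimator
and the k-group log-rank test, and to clinical covariates (MYCN
amplification, INSS stage 4, age over 18 months) with rank-sum tests on the
per-tumor MGS score.

Survival estimation and testing delegate to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster import hierarchy

from .containers import ExpressionMatrix, GeneSignature
from .divergence import _standardize_genes
from .scqpcr import rank_sum_test, signature_score

__all__ = [
    "SurvivalCohort",
    "TumorClasses",
    "CLASS_NAMES",
    "cluster_tumors",
    "km_estimate",
    "logrank_test",
    "clinical_splits",
]

CLASS_NAMES = ("MGS.High", "MGS.Int", "MGS.Low")


@dataclass
class SurvivalCohort:
    """Per-tumor survival time, event flag, and clinical covariates.

    ``table`` is indexed by tumor id with columns ``time`` (>= 0, any
    consistent unit), ``event`` (0 censored / 1 event) and optionally
    ``mycn_status`` (amplified | non-amplified | unknown), ``stage``
    (e.g. INSS category as string) and ``age_group`` ("<=18m" | ">18m").
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"cohort table needs a {col!r} column")
        if (t["time"] < 0).any():
            raise ValueError("survival times must be non-negative")
        if not set(t["event"].unique()) <= {0, 1}:
            raise ValueError("event must be 0/1")
        self.table = t.assign(time=t["time"].astype(float), event=t["event"].astype(int))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TumorClasses:
    """Per-tumor stratum label plus the mean MGS score of each stratum."""

    labels: pd.Series  # tumor id -> MGS.High / MGS.Int / MGS.Low
    class_scores: pd.Series  # stratum -> mean MGS score

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def cluster_tumors(
    expr: ExpressionMatrix,
    panel: GeneSignature | list[str],
    mgs: GeneSignature,
    k: int = 3,
) -> TumorClasses:
    """Ward-cluster tumors on the panel genes and name strata by MGS score.

    Expression of each panel gene is standardized across tumors before
    clustering; the tree is cut at ``k`` and clusters are renamed
    MGS.High/Int/Low by descending mean per-tumor MGS score.
    """
    genes = list(panel.genes) if isinstance(panel, GeneSignature) else list(panel)
    missing = [g for g in genes if g not in expr.data.columns]
    if missing:
        raise ValueError(f"panel genes absent from cohort matrix: {missing[:5]}")
    if k > len(expr.data):
        raise ValueError(f"k={k} exceeds number of tumors ({len(expr.data)})")
    if k != len(CLASS_NAMES):
        raise ValueError("stratum naming is defined for k=3")
    # per-gene Z across tumors; _standardize_genes returns genes x samples
    standardized = _standardize_genes(expr.data[genes]).T  # tumors x genes
    Z = hierarchy.linkage(standardized, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    mgs_score = signature_score(expr, mgs)
    means = mgs_score.groupby(raw).mean().sort_values(ascending=False)
    rename = {cluster_id: CLASS_NAMES[i] for i, cluster_id in enumerate(means.index)}
    labels = pd.Series([rename[r] for r in raw], index=expr.data.index, name="class")
    class_scores = pd.Series(
        {rename[c]: m for c, m in means.items()}, name="mean_mgs_score"
    )
    return TumorClasses(labels=labels, class_scores=class_scores)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of the survival function.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored`` and ``survival``.  With no
    censoring the estimate equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 not in times else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def logrank_test(times, events, groups) -> dict:
    """k-group log-rank test; chi-square statistic with k-1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if np.any(counts == 0):
        raise ValueError("every group needs at least one subject")
    res = multivariate_logrank_test(times, groups, events)
    chi2 = float(res.test_statistic)
    df = int(labels.size - 1)
    return {"chi2": chi2, "df": df, "p_value": float(res.p_value)}


def clinical_splits(
    mgs_scores: pd.Series, cohort: SurvivalCohort
) -> pd.DataFrame:
    """Rank-sum comparisons of the MGS score across clinical splits.

    Splits: MYCN amplified vs non-amplified (``unknown`` excluded), INSS
    stage 4 vs other, age >18 months vs <=18 months.  Only splits whose
    covariate column is present are computed; both strata must be non-empty.
    """
    t = cohort.table
    scores = mgs_scores.reindex(t.index)
    specs = []
    if "mycn_status" in t.columns:
        specs.append(
            ("MYCN", t["mycn_status"] == "amplified", t["mycn_status"] == "non-amplified")
        )
    if "stage" in t.columns:
        is4 = t["stage"].astype(str) == "4"
        specs.append(("Stage", is4, ~is4))
    if "age_group" in t.columns:
        older = t["age_group"] == ">18m"
        specs.append(("Age", older, ~older))
    if not specs:
        raise ValueError("no clinical covariate column present")
    rows = []
    for name, high_mask, low_mask in specs:
        a = scores[high_mask].dropna()
        b = scores[low_mask].dropna()
        if a.empty or b.empty:
            raise ValueError(f"empty stratum in clinical split {name!r}")
        stat, p = rank_sum_test(a.to_numpy(), b.to_numpy())
        rows.append(
            {
                "split": name,
                "n_high_risk": int(a.size),
                "n_low_risk": int(b.size),
                "median_high_risk": float(a.median()),
                "median_low_risk": float(b.median()),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("split")
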