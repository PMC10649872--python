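"""Genotype-by-time expression divergence, gene grouping, and set enrichment.

The divergence screen fits, per gene, an ordinary least-squares model

    expression ~ genotype + time + genotype:time

with genotype coded 0 (wild-type) / 1 (transgenic) and time numeric in
weeks.  The two-sided p-value of the interaction term measures divergence
of the two genotype trajectories over time; Benjamini-Hochberg adjustment
across genes controls the FDR and ``q < alpha`` selects genes.

Selected genes are standardized and grouped by Ward-criterion hierarchical
clustering on Euclidean distances (the ward.D2 convention: input distances
unsquared, squaring happens inside the merge criterion), and gene groups
are summarized as average-Z signature trajectories per genotype and time.
Over-representation of a gene group in supplied gene sets uses the
upper-tail hypergeometric test with BH adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSignature

__all__ = [
    "TimecourseDesign",
    "DivergenceFit",
    "fit_divergence",
    "cluster_gene_groups",
    "group_signature_trajectory",
    "signature_correlation",
    "ora_hypergeometric",
]

GENOTYPE_CODES = {"wild-type": 0, "transgenic": 1}


@dataclass
class TimecourseDesign:
    """Per-sample genotype and age (weeks) for the divergence model.

    ``table`` is indexed by sample id with columns ``genotype`` (either the
    strings ``wild-type``/``transgenic`` or already-coded 0/1) and ``age``
    (numeric weeks).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "genotype" not in t.columns or "age" not in t.columns:
            raise ValueError("design needs 'genotype' and 'age' columns")
        g = t["genotype"]
        if g.dtype == object:
            unknown = set(g.unique()) - set(GENOTYPE_CODES)
            if unknown:
                raise ValueError(f"unknown genotype labels: {sorted(unknown)}")
            t["genotype"] = g.map(GENOTYPE_CODES)
        t["genotype"] = t["genotype"].astype(int)
        if not set(t["genotype"].unique()) == {0, 1}:
            raise ValueError("design needs both genotypes present")
        t["age"] = t["age"].astype(float)
        for code in (0, 1):
            if t.loc[t["genotype"] == code, "age"].nunique() < 2:
                raise ValueError("each genotype needs >=2 timepoints")
        self.table = t

    @property
    def genotype(self) -> np.ndarray:
        return self.table["genotype"].to_numpy(dtype=float)

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)


@dataclass
class DivergenceFit:
    """Per-gene interaction estimates, p/q values, and the selection flag."""

    table: pd.DataFrame  # columns: beta_interaction, p, q, selected
    alpha: float

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def fit_divergence(
    expr: ExpressionMatrix, design: TimecourseDesign, alpha: float = 0.05
) -> DivergenceFit:
    """Per-gene genotype x time interaction OLS with BH selection.

    Vectorized across genes: one shared design matrix, closed-form OLS, and
    a t-test on the interaction coefficient with n - 4 residual degrees of
    freedom.  Noiseless data gives exact coefficients with p = 0.
    """
    if not expr.data.index.equals(design.table.index):
        raise ValueError("expression rows and design rows must align")
    g = design.genotype
    t = design.age
    X = np.column_stack([np.ones_like(g), g, t, g * t])
    n, k = X.shape
    if n <= k:
        raise ValueError("need more samples than model parameters")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design")
    Y = expr.data.to_numpy(dtype=float)  # samples x genes
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # k x genes
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[3, 3], 0.0))
    b_int = beta[3]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, b_int / np.where(se > 0, se, 1.0), np.inf * np.sign(b_int))
    tstat = np.where((se == 0) & (b_int == 0), 0.0, tstat)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "beta_interaction": b_int,
            "p": p,
            "q": q,
            "selected": q < alpha,
        },
        index=expr.data.columns,
    )
    return DivergenceFit(table=table, alpha=alpha)


def _standardize_genes(expr: pd.DataFrame) -> np.ndarray:
    """Per-gene Z across samples; rows of the result are genes."""
    mat = expr.to_numpy(dtype=float).T  # genes x samples
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (mat - mean) / sd


def cluster_gene_groups(
    expr: ExpressionMatrix, genes: list[str] | None = None, k: int = 3
) -> pd.Series:
    """Ward hierarchical clustering of standardized gene trajectories.

    Returns a gene -> group id (1..k) Series.  Group ids are relabelled so
    that group order follows the first occurrence in the input gene order,
    making assignments invariant to the arbitrary ids of the tree cut.
    """
    sub = expr.data if genes is None else expr.data[list(genes)]
    gene_names = list(sub.columns)
    if k > len(gene_names):
        raise ValueError(f"k={k} exceeds number of genes ({len(gene_names)})")
    Z = hierarchy.linkage(_standardize_genes(sub), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    groups = pd.Series([relabel[r] for r in raw], index=gene_names, name="group")
    return groups


def ward_linkage(points: np.ndarray) -> np.ndarray:
    """Ward-criterion linkage on raw observation rows (ward.D2 convention)."""
    return hierarchy.linkage(pdist(points), method="ward")


def group_signature_trajectory(
    expr: ExpressionMatrix,
    genes,
    design: TimecourseDesign,
) -> pd.DataFrame:
    """Mean +/- SD of the average-Z signature score per genotype x time.

    ``genes`` may be a GeneSignature or any iterable of gene symbols.
    Z-scores are per gene across all samples (ddof=1); the per-sample score
    is the mean Z over the signature genes.
    """
    gene_list = list(genes.genes) if isinstance(genes, GeneSignature) else list(genes)
    present = [g for g in gene_list if g in expr.data.columns]
    if not present:
        raise ValueError("no signature gene present in matrix")
    sub = expr.data[present]
    sd = sub.std(axis=0, ddof=1).replace(0.0, np.nan)
    z = (sub - sub.mean(axis=0)) / sd
    score = z.mean(axis=1, skipna=True).fillna(0.0)
    frame = design.table.assign(score=score)
    agg = (
        frame.groupby(["genotype", "age"])["score"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return agg


def signature_correlation(scores_a: pd.Series, scores_b: pd.Series) -> dict:
    """Pearson correlation between two per-sample signature scores."""
    joined = pd.concat([scores_a, scores_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared samples")
    a = joined.iloc[:, 0].to_numpy()
    b = joined.iloc[:, 1].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a score vector")
    r, p = stats.pearsonr(a, b)
    return {"pearson_r": float(r), "p_value": float(p), "n": int(len(joined))}


def ora_hypergeometric(
    group_genes, gene_sets: dict[str, GeneSignature] | dict[str, list[str]], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene group.

    For each set: with universe size M, set size K, group size n and
    overlap x, p = P[X >= x] for X ~ Hypergeometric(M, K, n).  BH-adjusted
    q values across sets.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    group = [g for g in dict.fromkeys(group_genes)]
    if not set(group) <= uni:
        raise ValueError("group genes must be contained in the universe")
    M, n = len(uni), len(group)
    rows = []
    for name, sig in gene_sets.items():
        members = list(sig.genes) if isinstance(sig, GeneSignature) else list(sig)
        members = [m for m in dict.fromkeys(members) if m in uni]
        if not members:
            raise ValueError(f"gene set {name!r} has no gene in the universe")
        K = len(members)
        x = len(set(members) & set(group))
        p = float(stats.hypergeom.sf(x - 1, M, K, n))
        rows.append({"set": name, "set_size": K, "overlap": x, "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    return table.sort_values("p", kind="stable")
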