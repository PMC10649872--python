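"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one assay — Hill-curve
viability plates, constant-ratio combination plates with a tunable Bliss
interaction, targeted single-cell qPCR Ct chips, two-genotype timecourse
expression, and a tumor cohort with class-dependent exponential survival —
and returns the hidden truth (labels, flags, classes) alongside the data so
downstream recovery can be scored without re-derivation.

All randomness flows through one :class:`SimConfig`; the same seed and
configuration reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtMatrix, ExpressionMatrix
from .dose_response import DoseResponseSeries
from .signatures import MGS, SC_PANEL
from .synergy import bliss_predicted_effect

__all__ = [
    "SimConfig",
    "simulate_dose_response",
    "simulate_combination",
    "default_archetypes",
    "simulate_ct_matrix",
    "simulate_timecourse",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Shared simulation knobs: seed, replicate count, noise level.

    ``noise_sd`` is in viability units (fraction of control) for plate
    generators, cycles for Ct generators and log2 units for expression
    generators.
    """

    seed: int = 0
    n_replicates: int = 3
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _truncated_normal(
    mean: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise around ``mean``, left-truncated at 0 (no upper bound)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return mean.copy()
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)


def hill_viability(doses, ic50: float, slope: float, floor: float) -> np.ndarray:
    """Hill curve: viability = floor + (1 - floor) / (1 + (d / ic50)^slope)."""
    d = np.asarray(doses, dtype=float)
    return floor + (1.0 - floor) / (1.0 + (d / ic50) ** slope)


def simulate_dose_response(
    hill_params: dict,
    doses,
    config: SimConfig,
    agent: str = "agent",
    condition: str = "cond",
    rng: np.random.Generator | None = None,
) -> DoseResponseSeries:
    """Replicated Hill-curve viabilities with truncated Gaussian plate noise."""
    ic50 = float(hill_params["ic50"])
    slope = float(hill_params["slope"])
    floor = float(hill_params.get("floor", 0.0))
    if ic50 <= 0 or slope <= 0:
        raise ValueError("ic50 and slope must be positive")
    if not 0.0 <= floor <= 1.0:
        raise ValueError("floor must lie in [0, 1]")
    d = np.asarray(doses, dtype=float)
    if d.ndim != 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("doses must be strictly increasing and positive")
    mean = hill_viability(d, ic50, slope, floor)
    rng = config.rng() if rng is None else rng
    viability = np.vstack(
        [_truncated_normal(mean, config.noise_sd, rng) for _ in range(config.n_replicates)]
    )
    return DoseResponseSeries(agent=agent, condition=condition, doses=d, viability=viability)


def simulate_combination(
    series_a: DoseResponseSeries,
    series_b: DoseResponseSeries,
    ratio: float,
    interaction: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> DoseResponseSeries:
    """Constant-ratio combination with a dose-uniform Bliss deviation.

    At pair i (dA_i, dB_i = ratio * dA_i) the true fraction affected is
    clamp[0,1](fa + fb - fa*fb + interaction) computed from the single
    agents' mean curves; interaction = 0 reproduces exact Bliss additivity.
    Replicate noise is the same truncated Gaussian as the single agents.
    """
    if series_a.doses.size != series_b.doses.size:
        raise ValueError("single-agent ladders differ in length")
    fa = 1.0 - np.clip(series_a.mean_viability(), 0.0, 1.0)
    fb = 1.0 - np.clip(series_b.mean_viability(), 0.0, 1.0)
    combined = np.clip(bliss_predicted_effect(fa, fb) + interaction, 0.0, 1.0)
    mean_viability = 1.0 - combined
    rng = config.rng() if rng is None else rng
    viability = np.vstack(
        [
            _truncated_normal(mean_viability, config.noise_sd, rng)
            for _ in range(config.n_replicates)
        ]
    )
    return DoseResponseSeries(
        agent=f"{series_a.agent}+{series_b.agent}",
        condition=series_a.condition,
        doses=series_a.doses.copy(),
        viability=viability,
        ratio_partner=(series_b.agent, float(ratio)),
    )


def default_archetypes(
    on_ct: float = 14.0, off_ct: float = 28.0, mitotic_high_ct: float = 16.0
) -> pd.DataFrame:
    """Mean-Ct archetypes over the 18-gene single-cell panel.

    Each cell type expresses its own 3 marker genes strongly (low Ct) and
    the other markers below detection; neuroblasts additionally express the
    9 mitotic genes, emulating mitotically dysregulated premalignant cells.
    """
    genes = list(SC_PANEL)
    arch = pd.DataFrame(off_ct, index=["neuroblast", "ganglion", "schwannian"], columns=genes)
    arch.loc["neuroblast", ["Phox2b", "hMYCN", "Dlk1"]] = on_ct
    arch.loc["ganglion", ["Gap43", "Dbh", "Tubb3"]] = on_ct
    arch.loc["schwannian", ["Sox10", "Col1a2", "S100a1"]] = on_ct
    arch.loc["neuroblast", list(MGS.genes)] = mitotic_high_ct
    return arch


def simulate_ct_matrix(
    archetypes: pd.DataFrame,
    mix: dict[str, float],
    n_cells: int,
    config: SimConfig,
    lod: float = 24.0,
    origin: str = "ganglion-day10",
) -> tuple[CtMatrix, pd.Series]:
    """Single-cell Ct chip from per-celltype archetype means.

    Cells are drawn from ``mix`` (proportions summing to 1), each cell's Ct
    is its archetype mean plus Gaussian noise (``config.noise_sd`` cycles),
    and any Ct at or beyond the limit of detection is recorded as
    not-detected.  Returns the matrix and the hidden true label per cell.
    """
    types = list(mix)
    props = np.array([mix[t] for t in types], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"cell-type proportions sum to {props.sum()}, not 1")
    unknown = [t for t in types if t not in archetypes.index]
    if unknown:
        raise ValueError(f"archetype rows missing for cell types: {unknown}")
    rng = config.rng()
    labels = rng.choice(types, size=n_cells, p=props)
    means = archetypes.loc[labels].to_numpy(dtype=float)
    ct = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    detected = ct < lod
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    ct_df = pd.DataFrame(ct, index=cell_ids, columns=archetypes.columns)
    ct_df = ct_df.where(pd.DataFrame(detected, index=cell_ids, columns=archetypes.columns))
    meta = pd.DataFrame({"origin": origin}, index=cell_ids)
    matrix = CtMatrix(
        ct=ct_df,
        detected=pd.DataFrame(detected, index=cell_ids, columns=archetypes.columns),
        lod=lod,
        meta=meta,
    )
    truth = pd.Series(labels, index=cell_ids, name="true_type")
    return matrix, truth


def simulate_timecourse(
    n_genes: int,
    diverging_fraction: float,
    effect: float,
    config: SimConfig,
    timepoints=(1.0, 2.0, 6.0),
    genotypes=("wild-type", "transgenic"),
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    common_slope_sd: float = 0.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Two-genotype timecourse with a divergent gene subset.

    Divergent genes (an exact ``round(diverging_fraction * n_genes)`` count,
    chosen at random) rise in the transgenic trajectory at +effect/2 log2
    units/week and fall in wild-type at -effect/2, so the genotype x time
    interaction coefficient equals ``effect``.  Null genes share one common
    trajectory in both genotypes.  Returns (expression, design table, truth
    flags).
    """
    if len(timepoints) < 2 or len(genotypes) < 2:
        raise ValueError("need >=2 timepoints and >=2 genotypes")
    rng = config.rng()
    n_div = int(round(diverging_fraction * n_genes))
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    divergent = np.zeros(n_genes, dtype=bool)
    divergent[rng.choice(n_genes, size=n_div, replace=False)] = True
    if effect == 0:
        divergent[:] = False

    rows, design_rows = [], []
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    common_slope = (
        rng.normal(0.0, common_slope_sd, size=n_genes)
        if common_slope_sd > 0
        else np.zeros(n_genes)
    )
    sample_ids = []
    for geno_idx, geno in enumerate(genotypes):
        geno_slope = np.where(divergent, (geno_idx - 0.5) * effect, 0.0)
        for t in timepoints:
            for rep in range(config.n_replicates):
                mean = baseline + (common_slope + geno_slope) * t
                noise = rng.normal(0.0, config.noise_sd, size=n_genes)
                rows.append(mean + noise)
                sid = f"{geno}_w{t:g}_r{rep}"
                sample_ids.append(sid)
                design_rows.append({"sample": sid, "genotype": geno, "age": float(t)})
    data = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=gene_ids)
    design = pd.DataFrame(design_rows).set_index("sample")
    expr = ExpressionMatrix(data, meta=design)
    truth = pd.Series(divergent, index=gene_ids, name="divergent")
    return expr, design, truth


def simulate_cohort(
    n_tumors: int,
    class_props=(0.2, 0.4, 0.4),
    hazard_ratios=(3.0, 1.5, 1.0),
    config: SimConfig | None = None,
    n_extra_panel_genes: int = 21,
    mgs_shift: float = 1.5,
    baseline_median: float = 60.0,
    horizon: float = 120.0,
    dropout_max: float = 240.0,
    clinical: bool = True,
) -> tuple[ExpressionMatrix, "pd.DataFrame", pd.Series]:
    """Tumor cohort with class-shifted panel expression and exponential survival.

    Three latent classes (High, Int, Low mitotic activity) with proportions
    ``class_props``:

    * expression: the 9 MGS genes and ``n_extra_panel_genes`` additional
      divergence-panel genes are shifted by +mgs_shift / 0 / -mgs_shift
      log2 units for the High/Int/Low classes, plus N(0, noise_sd) noise;
    * survival: event times exponential with class hazards
      ``hazard_ratios * log(2) / baseline_median``; censoring is
      administrative at ``horizon`` plus independent uniform dropout on
      (0, dropout_max);
    * clinical covariates (optional): MYCN amplification, INSS stage 4 and
      age >18 months are each more frequent in higher classes.

    Returns (expression, survival-and-clinical table, truth classes with
    values MGS.High/MGS.Int/MGS.Low).
    """
    config = config or SimConfig(noise_sd=1.0)
    props = np.asarray(class_props, dtype=float)
    hrs = np.asarray(hazard_ratios, dtype=float)
    if props.size != 3 or hrs.size != 3:
        raise ValueError("expect 3 class proportions and 3 hazard ratios")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = config.rng()
    class_names = ("MGS.High", "MGS.Int", "MGS.Low")
    cls = rng.choice(3, size=n_tumors, p=props)
    tumor_ids = [f"tumor{i:04d}" for i in range(n_tumors)]

    panel_genes = list(MGS.genes) + [f"panel{i:02d}" for i in range(n_extra_panel_genes)]
    shift_by_class = np.array([mgs_shift, 0.0, -mgs_shift])
    base = rng.normal(8.0, 1.0, size=len(panel_genes))
    mean = base[np.newaxis, :] + shift_by_class[cls][:, np.newaxis]
    data = mean + rng.normal(0.0, config.noise_sd, size=(n_tumors, len(panel_genes)))
    expr = ExpressionMatrix(pd.DataFrame(data, index=tumor_ids, columns=panel_genes))

    lam0 = np.log(2.0) / baseline_median
    lam = lam0 * hrs[cls]
    event_time = rng.exponential(1.0 / lam)
    dropout = rng.uniform(0.0, dropout_max, size=n_tumors)
    censor_time = np.minimum(horizon, dropout)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    table = pd.DataFrame({"time": time, "event": event}, index=tumor_ids)
    if clinical:
        p_mycn = np.array([0.6, 0.2, 0.05])[cls]
        p_stage4 = np.array([0.7, 0.4, 0.2])[cls]
        p_older = np.array([0.7, 0.5, 0.3])[cls]
        table["mycn_status"] = np.where(
            rng.uniform(size=n_tumors) < p_mycn, "amplified", "non-amplified"
        )
        table["stage"] = np.where(rng.uniform(size=n_tumors) < p_stage4, "4", "1-3")
        table["age_group"] = np.where(rng.uniform(size=n_tumors) < p_older, ">18m", "<=18m")
    truth = pd.Series([class_names[c] for c in cls], index=tumor_ids, name="true_class")
    return expr, table, truth
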