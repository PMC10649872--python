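"""Dose-response series, control normalization, and log10-dose AUC.

The potency summary used throughout the synergy analysis is the area under
the viability curve over log10(dose), integrated by the trapezoidal rule on
the observed dose ladder (no curve refitting).  Normalized AUC expresses
each curve as a fraction of the largest raw AUC in a comparison set, so the
least potent condition is anchored at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DoseResponseSeries",
    "AucResult",
    "normalize_viability",
    "auc_log_dose",
    "auc_per_replicate",
    "normalize_auc",
    "compare_auc",
]


@dataclass
class DoseResponseSeries:
    """One agent (or fixed-ratio combination) over an increasing dose ladder.

    Parameters
    ----------
    agent : str
        Agent label, e.g. ``"barasertib"`` or ``"barasertib+S63845"``.
    condition : str
        Assay condition, e.g. ``"MYCN+"`` / ``"MYCN-"``.
    doses : array
        Strictly increasing positive doses (molar).
    viability : array, shape (n_replicates, n_doses)
        Fraction of untreated control, non-negative.  Values above 1 are
        allowed (plate readers can report above control).
    ratio_partner : (str, float), optional
        For a constant-ratio combination indexed by agent-A dose: the second
        agent's label and the dose ratio dB/dA.
    """

    agent: str
    condition: str
    doses: np.ndarray
    viability: np.ndarray
    ratio_partner: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if self.doses.ndim != 1 or self.doses.size < 2:
            raise ValueError("need at least 2 doses")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.viability.shape[1] != self.doses.size:
            raise ValueError(
                f"viability has {self.viability.shape[1]} dose columns, "
                f"expected {self.doses.size}"
            )
        if self.viability.shape[0] < 1:
            raise ValueError("need at least one replicate")
        if np.any(self.viability < 0) or not np.all(np.isfinite(self.viability)):
            raise ValueError("viability must be finite and non-negative")

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[0]

    def mean_viability(self) -> np.ndarray:
        return self.viability.mean(axis=0)

    def log_doses(self) -> np.ndarray:
        return np.log10(self.doses)


@dataclass(frozen=True)
class AucResult:
    """Raw and comparison-set-normalized AUC for one labelled curve."""

    label: str
    raw_auc: float
    normalized_auc: float
    reference_label: str


def normalize_viability(raw_signal: np.ndarray, control_wells) -> np.ndarray:
    """Divide each well by its replicate's mean control signal.

    ``raw_signal`` is replicate x well; ``control_wells`` indexes the
    untreated wells.  Untreated controls therefore map to 1 on average
    within every replicate.
    """
    raw = np.atleast_2d(np.asarray(raw_signal, dtype=float))
    control_wells = np.asarray(control_wells, dtype=int)
    if control_wells.size == 0:
        raise ValueError("need at least one control well")
    control_mean = raw[:, control_wells].mean(axis=1, keepdims=True)
    if np.any(control_mean <= 0):
        raise ValueError("control mean must be positive in every replicate")
    return raw / control_mean


def auc_log_dose(series: DoseResponseSeries) -> float:
    """Trapezoidal integral of mean viability over log10(dose)."""
    return float(np.trapezoid(series.mean_viability(), series.log_doses()))


def auc_per_replicate(series: DoseResponseSeries) -> np.ndarray:
    """Trapezoidal AUC of each replicate's own viability curve."""
    x = series.log_doses()
    return np.trapezoid(series.viability, x, axis=1)


def normalize_auc(raw_aucs: dict[str, float]) -> dict[str, AucResult]:
    """Express each raw AUC as a fraction of the comparison set's maximum.

    The label with the maximum raw AUC (the least potent condition) is the
    reference and gets normalized AUC 1.  All series are assumed to share
    one dose ladder (identical log10-dose range).
    """
    if not raw_aucs:
        raise ValueError("empty comparison set")
    reference_label = max(raw_aucs, key=lambda lab: raw_aucs[lab])
    reference = raw_aucs[reference_label]
    if reference <= 0:
        raise ValueError("maximum raw AUC must be positive")
    return {
        lab: AucResult(lab, float(a), float(a / reference), reference_label)
        for lab, a in raw_aucs.items()
    }


def compare_auc(series_a: DoseResponseSeries, series_b: DoseResponseSeries) -> dict:
    """Two-sided two-sample t-test on per-replicate AUCs.

    Returns ``{"difference": mean_a - mean_b, "p_value": p}``.  With zero
    variance in both groups: identical means give p = 1 (no evidence in a
    degenerate comparison); distinct means give p at the float minimum.
    """
    if series_a.n_replicates < 2 or series_b.n_replicates < 2:
        raise ValueError("AUC comparison needs >=2 replicates per series")
    auc_a = auc_per_replicate(series_a)
    auc_b = auc_per_replicate(series_b)
    difference = float(auc_a.mean() - auc_b.mean())
    if np.var(auc_a) == 0.0 and np.var(auc_b) == 0.0:
        p = 1.0 if difference == 0.0 else float(np.finfo(float).tiny)
    else:
        p = float(stats.ttest_ind(auc_a, auc_b).pvalue)
    return {"difference": difference, "p_value": p}
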