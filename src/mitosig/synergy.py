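"""Bliss-additivity reference curves and AUC-based synergy/potency scoring.

For a constant-ratio combination of agents A and B, the Bliss independence
model predicts a combined fraction-affected fa + fb - fa*fb at every tested
dose pair.  A theoretical additivity curve is built from the two measured
single-agent curves, and:

* synergy  = normalized AUC(additive) - normalized AUC(combination)
  (positive = the combination kills more than independent action predicts);
* potency  = 1 - normalized AUC(combination)
  (0 when the combination is the least potent condition in the set).

Normalization is relative to the largest raw AUC within one combination
experiment — by default all measured curves for the experiment plus the
inferred additive curve, and in the two-condition workflow the union over
MYCN+ and MYCN- conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, auc_log_dose, normalize_auc

__all__ = [
    "SynergyResult",
    "bliss_predicted_effect",
    "additivity_curve",
    "score_combination",
    "score_experiment",
    "myc_selectivity_table",
]

_ADDITIVE_SUFFIX = " (Bliss additive)"


@dataclass(frozen=True)
class SynergyResult:
    """Synergy and potency of one combination under one condition."""

    combination_label: str
    condition: str
    auc_combo: float
    auc_additive: float
    synergy: float
    potency: float
    per_dose_excess: np.ndarray

    def as_dict(self) -> dict:
        d = {
            "combination": self.combination_label,
            "condition": self.condition,
            "auc_combo": self.auc_combo,
            "auc_additive": self.auc_additive,
            "synergy": self.synergy,
            "potency": self.potency,
        }
        return d


def bliss_predicted_effect(fa, fb):
    """Bliss independence: expected combined fraction-affected fa + fb - fa*fb.

    Accepts scalars or arrays in [0, 1]; symmetric in its arguments.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any((fa < 0) | (fa > 1)) or np.any((fb < 0) | (fb > 1)):
        raise ValueError("fraction-affected inputs must lie in [0, 1]")
    out = fa + fb - fa * fb
    return float(out) if out.ndim == 0 else out


def _fraction_affected(series: DoseResponseSeries) -> np.ndarray:
    # Bliss is defined on probabilities: clamp mean viability into [0, 1]
    # before converting (only here; AUCs keep unclipped viabilities).
    return 1.0 - np.clip(series.mean_viability(), 0.0, 1.0)


def additivity_curve(
    single_a: DoseResponseSeries,
    single_b: DoseResponseSeries,
    ratio: float,
    condition: str | None = None,
) -> DoseResponseSeries:
    """Theoretical Bliss-additive curve for the constant-ratio pair ladder.

    At pair index i the two agents are at doses (dA_i, dB_i = ratio * dA_i);
    the additive viability is 1 - bliss(fa_i, fb_i) with fractions affected
    taken from each single agent's mean curve.  The result is a synthetic
    one-replicate series on agent A's dose ladder.
    """
    if ratio <= 0:
        raise ValueError("dose ratio must be positive")
    if single_a.doses.size != single_b.doses.size:
        raise ValueError("single-agent dose ladders differ in length")
    expected_b = ratio * single_a.doses
    rel_err = np.abs(single_b.doses - expected_b) / expected_b
    if np.any(rel_err > 1e-6):
        raise ValueError(
            "agent-B doses do not match ratio * agent-A doses "
            f"(max relative error {rel_err.max():.3g})"
        )
    fa = _fraction_affected(single_a)
    fb = _fraction_affected(single_b)
    additive_viability = 1.0 - bliss_predicted_effect(fa, fb)
    return DoseResponseSeries(
        agent=f"{single_a.agent}+{single_b.agent}{_ADDITIVE_SUFFIX}",
        condition=condition or single_a.condition,
        doses=single_a.doses.copy(),
        viability=additive_viability[np.newaxis, :],
        ratio_partner=(single_b.agent, float(ratio)),
    )


def score_combination(
    combo: DoseResponseSeries,
    single_a: DoseResponseSeries,
    single_b: DoseResponseSeries,
    ratio: float | None = None,
    comparison_set: list[DoseResponseSeries] | None = None,
) -> SynergyResult:
    """Score one measured combination against its Bliss-additive reference.

    ``comparison_set`` defaults to the three measured series; the additive
    curve is always added before normalization so both areas are expressed
    on the same scale.
    """
    if ratio is None:
        if combo.ratio_partner is None:
            raise ValueError("ratio not given and combo has no ratio_partner")
        ratio = combo.ratio_partner[1]
    additive = additivity_curve(single_a, single_b, ratio, condition=combo.condition)
    if comparison_set is None:
        comparison_set = [single_a, single_b, combo]
    members = list(comparison_set) + [additive]
    raw = {}
    for s in members:
        key = f"{s.agent} [{s.condition}]"
        raw[key] = auc_log_dose(s)
    normed = normalize_auc(raw)
    combo_key = f"{combo.agent} [{combo.condition}]"
    additive_key = f"{additive.agent} [{additive.condition}]"
    auc_combo = normed[combo_key].normalized_auc
    auc_additive = normed[additive_key].normalized_auc
    excess = _fraction_affected(combo) - (1.0 - additive.mean_viability())
    return SynergyResult(
        combination_label=combo.agent,
        condition=combo.condition,
        auc_combo=auc_combo,
        auc_additive=auc_additive,
        synergy=auc_additive - auc_combo,
        potency=1.0 - auc_combo,
        per_dose_excess=excess,
    )


def score_experiment(
    experiment: dict[str, tuple[DoseResponseSeries, DoseResponseSeries, DoseResponseSeries]],
    ratio: float,
) -> dict[str, SynergyResult]:
    """Score one combination experiment across conditions with a shared reference.

    ``experiment`` maps condition -> (combo, single_a, single_b).  The
    normalization set is the union of every measured series and every
    additive curve across all conditions, so the least potent single agent
    across both MYCN states anchors normalized AUC = 1.
    """
    shared: list[DoseResponseSeries] = []
    for combo, a, b in experiment.values():
        shared.extend([a, b, combo])
    results = {}
    for condition, (combo, a, b) in experiment.items():
        results[condition] = score_combination(
            combo, a, b, ratio=ratio, comparison_set=shared
        )
    return results


def myc_selectivity_table(
    results_pos: dict[str, SynergyResult],
    results_neg: dict[str, SynergyResult],
    condition_pos: str = "MYCN+",
    condition_neg: str = "MYCN-",
) -> pd.DataFrame:
    """Rank combinations by MYCN selectivity of synergy, then potency.

    Both inputs map combination label -> SynergyResult for the matching
    condition.  Ranking is lexicographic on (delta synergy, delta potency),
    descending, with ties broken by combination label for determinism.
    """
    missing = set(results_pos) ^ set(results_neg)
    if missing:
        raise ValueError(f"unmatched condition pairs for combinations: {sorted(missing)}")
    rows = []
    for label in sorted(results_pos):
        rp, rn = results_pos[label], results_neg[label]
        rows.append(
            {
                "combination": label,
                f"synergy_{condition_pos}": rp.synergy,
                f"synergy_{condition_neg}": rn.synergy,
                f"potency_{condition_pos}": rp.potency,
                f"potency_{condition_neg}": rn.potency,
                "delta_synergy": rp.synergy - rn.synergy,
                "delta_potency": rp.potency - rn.potency,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["delta_synergy", "delta_potency", "combination"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
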