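"""Stratify a tumor cohort by mitotic-signature expression and test survival.

Simulates a 475-tumor cohort whose latent classes shift the mitotic panel
and carry hazard ratios 3 / 1.5 / 1, recovers MGS.High / MGS.Int / MGS.Low
strata by Ward clustering, and runs the log-rank test plus clinical splits.
"""

from mitosig.cohort import (
    CLASS_NAMES,
    SurvivalCohort,
    clinical_splits,
    cluster_tumors,
    km_estimate,
    logrank_test,
)
from mitosig.scqpcr import signature_score
from mitosig.signatures import MGS
from mitosig.simulate import SimConfig, simulate_cohort

expr, clinical, truth = simulate_cohort(475, config=SimConfig(seed=12, noise_sd=1.0))
classes = cluster_tumors(expr, list(expr.data.columns), MGS)
print("stratum sizes:", dict(classes.counts()))
print(f"agreement with simulated classes: {(classes.labels == truth).mean():.1%}")

lr = logrank_test(clinical["time"], clinical["event"], classes.labels.to_numpy())
print(f"3-group log-rank: chi2={lr['chi2']:.1f} df={lr['df']} p={lr['p_value']:.2e}")

for name in CLASS_NAMES:
    sub = clinical[classes.labels == name]
    km = km_estimate(sub["time"], sub["event"])
    below = km[km["survival"] <= 0.5]
    median = f"{below['time'].iloc[0]:.0f} mo" if len(below) else "not reached"
    print(f"  {name}: n={len(sub)}, median survival {median}")

splits = clinical_splits(signature_score(expr, MGS), SurvivalCohort(clinical))
print(splits[["n_high_risk", "n_low_risk", "p_value"]].to_string())
print("MGS.High tumors die fastest and MGS scores are higher in the")
print("MYCN-amplified / stage-4 / older strata — the poor-prognosis pattern.")
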