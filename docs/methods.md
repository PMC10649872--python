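# Methods

This note records the models each stage implements, the defaults and why
they are set where they are, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Dose–response summaries and Bliss synergy

A dose–response series is a strictly increasing positive dose ladder with a
replicate × dose matrix of viabilities (fraction of untreated control;
values above 1 are retained, since plate readers can report above control
and clipping would bias the AUCs of weak agents). The potency summary is
the trapezoidal integral of mean viability over log₁₀(dose) on the observed
ladder — no Hill refit or interpolation precedes integration, so the "curve"
is exactly the plotted dose series and the summary cannot fail to converge.
Trapezoidal integration is exact for the piecewise-linear curve being
summarized, which is why the test suite can hold it to a dense-grid oracle
at 1e-9 relative.

Normalized AUC divides each raw AUC by the maximum in a comparison set, so
the least potent condition sits at 1 and `1 − AUC` reads as potency. The
comparison set for a combination experiment defaults to every measured
series across both MYCN conditions plus the inferred additive curves, so
synergy compares like-normalized areas; any other set can be passed
explicitly.

Bliss independence predicts combined fraction affected `fa + fb − fa·fb`.
Fractions affected are `1 − viability` with viability clamped to [0,1] for
this conversion only, because Bliss operates on probabilities; AUCs keep
the unclamped values. The additive curve evaluates the prediction at each
tested constant-ratio dose pair using the single agents' mean curves
(mean-then-predict; replicate-resampled alternatives would add variance
without changing the estimand) and is validated against the declared ratio
at 1e-6 relative tolerance.

Replicate-level AUC comparison uses a two-sided two-sample t-test on
per-replicate AUCs. Degenerate zero-variance inputs are answered without
NaNs: identical groups give p = 1 (a degenerate comparison carries no
evidence), a zero-variance offset gives p at the smallest positive float.

Combination ranking for MYCN selectivity is lexicographic on (Δsynergy,
Δpotency), descending, with label-alphabetical tie-breaks — both criteria
matter but no weighting between them is defensible, so the primary
criterion is explicit and deterministic.

## Single-cell qPCR

Detected reactions map to log2 expression as `LOD − Ct`, floored at 0;
not-detected reactions are 0. The default LOD is 24 cycles. Signature
scores are the mean per-gene Z-score over the signature's genes, with
Z-scores computed across **all** cells before any classification — the
reference population is locked pre-exclusion, so removing cells afterwards
never changes a score. Z uses the sample SD (ddof = 1, the R `scale()`
convention). Zero-variance or absent signature genes are dropped with a
warning rather than propagating undefined Z; a signature with no usable
gene is an error, and a signature whose genes are all flat scores 0.

Cell typing applies strict-inequality rules in a fixed precedence:
Schwannian score > 0.75 first, then neuroblast (> 0 and > ganglion), then
ganglion (> 0 and > neuroblast); everything else — including exact
neuroblast/ganglion ties — is excluded. Precedence matters only for cells
satisfying the Schwannian rule and a marker rule simultaneously; Schwannian
wins. Classification is deterministic and invariant to cell order.

Rank-sum comparisons use the exact Mann–Whitney null when the pooled sample
is ≤ 20 and tie-free (where exactness is cheap and the normal approximation
is worst), and the tie-corrected normal approximation otherwise.

## Divergence screen

Expression is modelled per gene as
`y = β₀ + β₁·genotype + β₂·t + β₃·genotype·t + ε` with genotype coded 0/1
and time numeric in weeks (1, 2, 6 by default) — divergence "over time" is
a trend contrast, so time enters numerically rather than as a factor. The
fit is closed-form OLS vectorized across genes (one shared design matrix),
with a t-test on β₃ at n − 4 residual df and Benjamini–Hochberg adjustment
across genes; `q < α` (default α = 0.05) selects. The model formula is a
documented stand-in for the published screen whose exact contrast structure
is not restated here; it is configurable at the design-table level and the
suite verifies its calibration (global-null false-selection within the α
budget) rather than equivalence to any external fit.

Gene grouping standardizes each selected gene to Z across samples and
applies Ward-criterion agglomerative clustering on Euclidean distances —
the `ward.D2` convention, with distances unsquared on input and squared
inside the merge criterion. scipy's `linkage(…, "ward")` implements exactly
this; the test suite pins it to a brute-force minimal-variance-increase
merge oracle on 8-point instances. Cluster ids from the tree cut are
relabelled by first occurrence in gene order so assignments are stable.

Over-representation of a gene group in supplied sets (GMT) is the upper-tail
hypergeometric p (`P[X ≥ x]` with universe M, set K, group n), BH-adjusted
across sets. Gene sets are flat lists; no ontology structure is modelled.

## Cohort stratification and survival

Tumors are standardized per gene and Ward-clustered on the divergence
panel; the k = 3 cut is renamed MGS.High / MGS.Int / MGS.Low strictly by
descending mean MGS score, which makes the naming independent of the
arbitrary cluster ids. Kaplan–Meier estimation and the k-group log-rank
test (aggregated risk sets at tied event times, χ² with k − 1 df) delegate
to lifelines; the tests hold them to hand-computed product-limit values and
a per-event-time hypergeometric-moment oracle. Clinical splits compare the
per-tumor MGS score by rank-sum across MYCN amplified vs non-amplified
(tumors with unknown status are excluded from this split only), INSS
stage 4 vs other, and age > 18 vs ≤ 18 months. The pipeline is agnostic to
the survival time unit as long as it is consistent.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical shape* each stage assumes, with
ground truth returned alongside:

* **Plates** — viability follows a Hill curve
  `floor + (1−floor)/(1 + (d/IC50)^slope)`; replicates add Gaussian noise
  left-truncated at 0 (proper truncation, not clipping, so variance scales
  smoothly; no upper truncation because >100%-of-control readings are
  real). Combinations evaluate Bliss at each constant-ratio pair plus a
  dose-uniform interaction term, clamped to [0,1]; interaction = 0 is exact
  additivity, making zero-synergy recovery a sharp test. Default plate
  noise SD 0.05 viability units, 3 replicates — typical for resazurin
  assays and unstated by the source assays.
* **Single-cell chips** — each cell draws its type from a mixing
  proportion, Ct = archetype mean + N(0, 1 cycle), and Ct ≥ LOD records as
  not-detected. Default archetypes express each type's 3 markers at Ct 14
  and foreign genes beyond the LOD, with the 9 mitotic genes active in
  neuroblasts. No amplification chemistry, chip-layout or dropout-bias
  artifacts are modelled.
* **Timecourses** — divergent genes (an exact constructed count) carry
  slope +effect/2 in the transgenic and −effect/2 in the wild-type
  trajectory, so the interaction coefficient equals `effect`; null genes
  share one trajectory. Noise N(0, 0.4 log2 units) by default.
* **Cohorts** — three latent classes shift a 30-gene panel (9 MGS + 21
  panel genes) by ±1.5 log2 units around per-gene baselines with N(0,1)
  noise; event times are exponential with class hazard ratios (default
  3 / 1.5 / 1 and a 60-month baseline median), censoring is administrative
  at 120 months plus uniform dropout on (0, 240) — the simplest mechanism
  satisfying the independent-censoring assumption of KM. Clinical
  covariates are Bernoulli with class-dependent frequencies.

Because noise levels are package choices (the source assays publish none),
passing tests demonstrate the *machinery* — estimator correctness,
calibration, recovery under stated separations — not performance on real
microarray or Fluidigm data, which carry batch structure, probe effects and
dropout these generators deliberately omit. Real data in the same CSV
shapes flow through the identical readers and functions.

## Problem sizes, determinism, degenerate inputs

The verification suite uses desk-scale sizes chosen to make its claims
statistically meaningful: 500 seeded plate simulations for synergy sign
agreement, 1000 cells for classifier recovery, 200 × 1000-gene null
datasets for FDR calibration, 100 random 8-gene instances for the Ward
oracle, 1000 two-group null simulations for log-rank calibration, and a
475-tumor cohort for the end-to-end survival split.

All randomness flows through numpy `default_rng` seeded from a single
configuration; identical seeds give bit-identical outputs, including
through the CLI (verified byte-for-byte). Known degenerate inputs have
pinned behaviour: single-dose ladders, non-increasing ladders, zero/negative
control means, empty groups or cohorts, rank-deficient designs, k larger
than the item count, and empty universes all raise `ValueError` with a
message naming the violated precondition; identifiers are case-sensitive
exact strings with no mouse/human symbol aliasing.

## Known limitations

* The AUC comparison test and the divergence model are documented
  stand-ins for under-specified published procedures (see above); both are
  calibrated, neither is claimed equivalent.
* Synergy is Bliss-only by design — no Loewe, ZIP or HSA references, no
  response-surface fitting, and no IC50 reporting as a headline output.
* Survival analysis is univariate KM/log-rank; no Cox modelling or
  covariate adjustment.
* The stratum naming rule requires k = 3; other k values would need their
  own naming convention.
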