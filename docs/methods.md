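# Methods

## Model

All analyses rest on the Andrich rating scale model (RSM). A person of
ability θ (logits) responding to an item of difficulty δ on a shared ordinal
rubric 0..m has

    P(X = k) ∝ exp( Σ_{j≤k} (θ − δ − τ_j) ) = exp( k(θ − δ) − Σ_{j≤k} τ_j ),

with the empty sum equal to zero and one threshold vector τ (length m,
Σ τ_j = 0) shared by every item of an instrument. The RSM rather than the
partial credit model is the right structure here because every checklist item
uses the same 3-point rubric; a per-item threshold model would spend
parameters the data cannot support at N ≈ 41. With m = 1 the model reduces
exactly to the dichotomous Rasch model. Probabilities are computed in log
space with max-subtraction, so measures of |θ − δ| > 30 logits are safe.

## Estimation

Joint maximum likelihood (JMLE/UCON): alternating damped Newton updates on
the raw-score residuals,

    θ_n += (r_n − Σ_i E_ni) / Σ_i W_ni
    δ_i −= (s_i − Σ_n E_ni) / Σ_n W_ni
    τ_j += (E[#{X ≥ j}] − #{x ≥ j}) / Σ_ni G_j(1 − G_j),   G_j = P(X ≥ j)

with E and W the model-expected cell score and its variance. Steps are capped
at ±1 logit per sweep; the cap does not move the fixed point, it only keeps
early sweeps stable when margins are near the boundary. Update order within a
sweep is persons, then items, then thresholds. After every sweep the
identification constraints (mean δ = 0 over non-extreme items, Σ τ = 0) are
re-imposed by likelihood-preserving translations. Starting values are PROX
log-odds of the raw margins: θ⁰ = ln(r′/(R − r′)), δ⁰ = −ln(s′/(S − s′))
centred, τ⁰_j = ln(c_{j−1}/c_j) from the overall category counts, centred.

Convergence requires both the largest absolute score residual ≤ 0.01 and the
largest parameter move ≤ 0.001 logits within at most 100 sweeps — more
precision than any two-decimal report consumes. Non-convergence is returned
(flagged and warned), never hidden. Missing cells are simply excluded from
every sum.

**Extreme scores.** Zero and perfect raw scores have no finite maximiser.
Persons and items at the boundary are removed (iteratively, since dropping a
ceiling person can push an item to the boundary), the core is fitted, and the
extremes are then assigned finite measures by solving their estimating
equation with the raw score pulled in by 0.3 score points against the fixed
co-parameters. They are flagged, excluded from the anchoring means, and still
plotted and summarised — posttest assessments of an effective training have a
real ceiling, so finite ceiling measures are a requirement, not a corner case.

**Standard errors** are model-based Fisher information, SE = 1/√(Σ W).

**Bias.** JMLE is inconsistent at fixed item count: measures inflate by
roughly L/(L−1) for L items. The default fit applies no correction, because
the downstream pre/post comparisons are shift comparisons on one common scale
and the package's reporting tradition leaves measures uncorrected. A
documented `bias_correct` option rescales measures by (L−1)/L; simulation
(500 persons × 13 items) shows it brings the mean absolute item-difficulty
error from ≈0.17 to ≤0.1 logits while leaving correlations (≈0.998)
untouched.

## Stacking and racking

Both arrangements run **one joint calibration** — no anchored two-step
equating. Stacking concatenates occasions by rows (2N × I): item difficulties
are shared across occasions, each person gets one ability per occasion, and
the N paired ability differences measure individual skill change. Racking
concatenates by columns (N × 2I): abilities are shared, each item gets one
difficulty per occasion, and the I paired difficulty differences measure how
much each skill eased. Differences are always reported as post − pre
(negative = easier item), with the magnitude alongside since difficulty drops
are conventionally quoted as positive numbers. Occasion tags "P" (pretest)
and "0" (posttest) prefix entity identifiers in stacked/racked output and
Wright maps.

The paired test is the Wilcoxon signed-rank: zeros dropped, midranks for
ties, exact two-sided p by full 2ⁿ enumeration of sign assignments for
n ≤ 12 (4096 enumerations are instant, and beyond that the approximation
error is negligible), otherwise the normal approximation with tie-corrected
variance and a 0.5 continuity correction. Identical pre and post matrices
produce all-zero differences; that case returns no test (with a warning)
because a signed-rank test on all zeros carries no evidence in either
direction.

The difficulty cross-plot median-centres the pre and post axes and flags
items above the identity line — items whose difficulty dropped less than the
typical item's — as still-difficult skills needing follow-up training.

## Quality panel

* Separation/reliability from measures and SEs: SD² the sample variance of
  the measures (non-extreme entities only), MSE = mean(SE²), true variance
  T = max(SD² − MSE, 0), reliability R = T/SD², separation G = √(T/MSE);
  R = G²/(1+G²) by construction.
* Cronbach's alpha on listwise-complete persons, definitional formula with
  sample (ddof = 1) variances.
* Variance explained by the measures: the variance of the model-expected
  scores E over observed cells against the mean model variance W, reported as
  100·Var(E)/(Var(E)+mean W). This is an expected-value decomposition; the
  observed-data analogue used by some packages agrees with it to the extent
  the model fits, and this form is exactly reproducible. Unidimensionality
  screening follows the usual rule of thumb (≥ 40% is strong).
* First residual contrast: largest eigenvalue of the item × item correlation
  matrix of standardised residuals (pairwise-complete), reported both as an
  eigenvalue and as its share of unexplained variance in percent of the
  total, so either convention can be read off. Undefined below 3 items.
* Infit (information-weighted) and outfit (unweighted) mean squares per
  person and item; ≈1 under model fit.

## Synthetic data

The generator emulates the target study's measurement situation: N = 41
trainees; 11 (infant) or 13 (toddler) items equally spaced over [−2, +2]
logits; thresholds (−1, +1); pretest abilities Normal(0.3, 1.0); a uniform
training effect of 2.7 (infant) or 3.3 (toddler) logits plus person-level
noise with SD 0.5 — chosen once so that simulated pre/post logit ranges span
roughly 4 logits each, the spread a heterogeneous volunteer cohort shows —
and optional item-specific shifts γ_i for skill blocks that resist training
(e.g. MUAC measurement). One random stream per call, consumed in a fixed
order (abilities, effect noise, pre cells row-major, post cells row-major,
missingness), so a seed pins every byte of output.

What it deliberately does **not** emulate: observer/rater disagreement (one
reconciled rating per person × item × occasion is assumed), drop-out between
occasions, learning during the assessment itself, or local item dependence
within skill dimensions. Passing tests therefore demonstrate that the
*analysis machinery* recovers person and item change under the model's
assumptions at the study's size — not that real observer-scored data meet
those assumptions.

## Numerical and design choices

* Category codes must be consecutive integers from 0; an unobserved category
  stops calibration with an instruction to collapse (`--collapse` renumbers).
  The declared scale maximum is kept even when the top category is unobserved
  in one occasion.
* Identifier matching is exact and case-sensitive; silent fuzzy matching
  could pair the wrong rows in a pre/post design.
* Ties in Wright-map bins sort lexicographically; rendering is deterministic
  and parseable, with M/S/T landmarks at the mean, ±1 SD and ±2 SD of each
  margin. The monospace text block is the primary artifact; PNG is a thin
  optional layer.
* The whole pipeline is deterministic: a fixed seed reproduces the report
  bundle byte-for-byte.
* Test problem sizes: oracle equivalence uses 5×4 and 6×5 matrices against a
  0.01-logit coordinate-ascent grid search of the joint likelihood; recovery
  simulations use 200–500 persons; effect recovery averages 20 study-shaped
  replicates; the signed-rank null uses 2000 replicates of n = 20.

## Known limitations

* JMLE bias (above); CMLE/MMLE and Warm's WLE are out of scope.
* No rater-facet modelling: if observers differ systematically in severity,
  their effect is absorbed into person measures.
* The stacking/racking arrangement assumes the instrument itself is stable
  across occasions apart from the modelled difficulty shifts; strong
  multidimensional change would violate the shared-threshold structure.
* Exact signed-rank enumeration stops at n = 12 by design; at larger n the
  tie-corrected normal approximation is used.
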