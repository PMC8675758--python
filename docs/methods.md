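# Methods

This note documents the model, the numerical choices and the synthetic
data generator, and states what the test suite does and does not
establish about real clinical data.

## Weekly networks

Correction events (date, sender, receiver) are aggregated into
contiguous half-open one-week windows anchored at the earliest roster
entry date. Any fixed anchor removes day-of-week periodicity equally;
anchoring at the first entry makes window indices reproducible from the
roster alone. Every resident whose tenure (closed interval
[entry, exit]) intersects a window is a node that week, including
residents who neither gave nor received corrections — a resident's
centrality must be defined for every week of tenure for per-resident
means to be well defined. Repeated same-pair corrections within a week
accumulate as integer edge weight; a `binary_edges` flag collapses them
to 1 for sensitivity analysis. Events are cross-validated first: events
naming unknown residents or dated outside either participant's tenure
are dropped with per-reason counts (archival records plausibly contain
entry/exit boundary noise; dropping with a report preserves
auditability, and the operation is idempotent).

## Centrality model

Hierarchy position is the Perron eigenvector of

    M = Wᵀ + εJ,   ε > 0,

max-normalized so the top score is 1. The in-edge (column) orientation
is the only one consistent with the pecking-order reading of a
negatively valenced network: a node's score aggregates the scores of
those who correct it, so the most-corrected-by-the-corrected resident
scores highest and sits lowest. On the canonical four-node pecking graph
{C→B, D→B, B→A} the implementation yields score(A) > score(B) >
score(C) = score(D) across ε ∈ {1e-2, 1e-4, 1e-6}.

**Why ε.** Weekly correction graphs are sparse, usually reducible and
often nilpotent; the unperturbed leading eigenvector is then degenerate
or identically zero. Adding the teleport floor εJ makes M strictly
positive, hence primitive, so the leading eigenvector is unique, simple
and strictly positive (Perron–Frobenius). ε defaults to 1e-4 and is
configurable; orderings on worked examples are stable from 1e-2 down to
1e-6, and as ε grows large the scores flatten toward all-equal.

**Solver.** Power iteration with an adaptive Rayleigh shift: the iterate
is y = Mx + λ̂x with λ̂ the current Rayleigh quotient. The shift leaves
eigenvectors untouched while strictly damping rotational modes —
directed cycles make M near-periodic, with several eigenvalue moduli
tied with the Perron root up to O(ε), where the unshifted iteration
cannot converge in any reasonable budget. Convergence is judged on a
three-iteration window of max-norm changes of the normalized iterate
(complex subdominant modes make the one-step change dip periodically
below its true level) and the remaining error is extrapolated through
the estimated contraction rate; the default tolerance is 1e-10 with an
iteration cap of 10,000. Hitting the cap returns the current vector
flagged non-converged with a warning rather than failing the run. A
dense full-eigendecomposition oracle (≤ 50 nodes) provides an
independent route used by the tests; across 200 random digraphs
(DAGs, disconnected graphs, mixed integer/continuous weights, ≤ 12
nodes) the two routes agree to better than 1e-8 at all three ε levels.

## Hierarchy measures

A resident's trajectory is their score in every window their tenure
intersects, correction-free weeks included (where the score is the
ε-floor value). Four summaries follow: maximum and mean over the whole
trajectory, and maximum and mean over the final min(4, n) weeks ("last
month"). Residents observed fewer than four weeks use their whole
tenure — no minimum-tenure exclusion is applied by default, because
silently dropping short stays would bias the climb comparison; a
`min_weeks` knob enables exclusion-based sensitivity analysis. By
construction the last-month maximum can never exceed the overall
maximum; the mean comparison is the substantive (stochastic) half of the
climb hypothesis.

## Inference

**Climb tests.** Per resident, (overall, last-month) pairs for each of
the two measure families enter a Wilcoxon signed-rank test: zero
differences dropped before ranking (Wilcoxon's original convention and
the common statistical-package default), average ranks for ties,
tie-corrected normal variance, 0.5 continuity correction, two-sided p.
The implementation reproduces `wilcox.test(paired=TRUE, correct=TRUE,
exact=FALSE)` to at least 7 decimals and its V statistic exactly; the
exact 2ⁿ enumeration agrees with the approximate p to < 0.03 for n ≥ 7
(at n ≤ 6 the intrinsic error of any continuity-corrected normal
approximation can exceed that). An all-zero-difference sample makes the
test undefined; the unit analysis reports this as "no hierarchy
movement" instead of failing.

**Graduation models.** Four logistic regressions (Model 1–4: last-month
maximum, last-month mean, overall maximum, overall mean), each with the
shared covariates age, LSI-R, minority-race indicator and days in
program (raw days). Estimation is maximum likelihood via IRLS
(statsmodels Logit); standard errors come from the inverse observed
information and p-values are Wald, with significance stars at
0.05/0.01/0.001. Fit statistics obey deviance = −2ℓ, AIC = deviance +
2k, BIC = deviance + k·ln n for k fitted terms. Detected separation
(Newton failure or |β| > 15) flags the fit non-converged; estimates are
still reported with a warning. Measures without variation (e.g. a unit
with zero corrections) skip their model with a note. No
multiple-testing correction is applied across the four models — they are
deliberately reported side by side as in standard practice for this
design — and this is a caveat for interpretation. Units with fewer than
20 complete residents carry a small-sample warning. Predicted
probability curves evaluate the inverse logit along a measure grid with
other terms held at sample means (mode for the binary race indicator).

## Synthetic unit generator

The generator produces roster and event tables with the structure the
analysis assumes, plus ground truth for recovery tests. Defaults (all
configurable) describe a large unit and were chosen once as the
package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_beds` | 80 | bed capacity; occupancy never exceeds it |
| `arrival_rate` | 0.7/day | Poisson arrivals before bed thinning (≈ full occupancy) |
| `mean_tenure_days`, `tenure_sd_days` | 135, 35 | truncated-normal stay, min 14 days |
| `span_days` | 604 | observation span (≈ 350 residents at defaults) |
| `corrections_per_resident_week` | 1.5 | expected weekly corrections per present resident |
| `rank_growth_rate` | 0.5/week | latent-rank drift (seniority climb) |
| `rank_noise_sd` | 0.8/√week | random-walk heterogeneity in climbing |
| `rank_preference_temperature` | 1.0 | softness of the down-rank correction preference |
| `grad_intercept`, `grad_rank_coef`, `grad_lsi_coef` | 1.9, 1.0, −0.05 | graduation logit: intercept + coef·(standardized final rank) + coef·(LSI-R − 26) |

Each resident's latent rank starts at zero on entry (new arrivals are
lowest-ranked) and performs a drifting random walk per week present.
Weekly corrections are Poisson across ordered co-present pairs with mean
proportional to σ((rank_s − rank_v)/temperature), so corrections flow
predominantly down-rank and the most junior residents receive the most;
the total is scaled to the per-resident rate. Graduation applies
`grad_rank_coef` to the *within-unit standardized* final rank: raw final
rank scales with drift × tenure, so a raw-rank coefficient would
entangle the base graduation rate with the effect size, whereas
standardization decouples them. Covariates (age ~ N(29, 8.6) ≥ 18,
LSI-R ~ N(26, 7) ≥ 0 rounded, minority ~ Bernoulli(0.2)) match the
scales typical of correctional TC populations, and realized default
moments land on those scales: graduation ≈ 0.80–0.86, days in program
≈ 120, beds-bounded census. All randomness derives from the single
config seed; identical configs give byte-identical output files.

**Identifiability of the graduation effect.** Because days in program is
a regression control and the rank drift is proportional to tenure, the
recoverable part of the rank→graduation effect is the random-walk
component of final rank, observed only through the correction network.
The default noise (0.8/√week) and correction volume (1.5/resident-week)
were set so that this component is genuinely expressed in the measures
(weekly networks remain sparse, density ≈ 2%): with a designed strong
positive rank effect, all four hierarchy coefficients come out negative
in essentially every simulated unit of ~300 residents, while under a
null rank effect the Wald test on a hierarchy coefficient holds its
nominal 5% size. At 16 beds over the same span (≈ 70 residents),
recovery power drops sharply relative to 80 beds — small units
genuinely under-identify the hierarchy.

**What the generator does not emulate.** Committee review of correction
legitimacy, reciprocity/revenge dynamics, dormitory substructure,
staff-driven interventions, seasonal intake patterns, censoring of
residents present at the span boundaries (tenures are clipped to the
observation span), and any mechanistic tenure↔graduation link beyond
their mutual association with rank. Passing recovery tests therefore
shows the *pipeline* measures what it claims to measure under a
self-organizing-hierarchy generative account — not that real TC units
follow that account.

## Problem sizes and determinism

Tests and the acceptance script run at deliberately compact sizes chosen
as the package's own study conditions: single units of ~70–350
residents, 20-seed batteries for directional claims, 200 replicates for
size calibration, 200-graph batteries for solver equivalence. Every
stochastic path is seeded; reruns are byte-identical, and the pipeline
writes a manifest (config, seed, version) alongside its artifacts.

## Known limitations

- ε-perturbed, weighted, max-normalized centrality is one well-posed
  reconstruction of "eigenvector centrality on a weekly correction
  network"; other conventions (unweighted, sum-normalized, cumulative
  networks) would give different absolute scores, though orderings are
  stable in our sensitivity checks.
- The four measures are summaries of a trajectory; no within-resident
  dynamic model (slopes, change-points) is fitted.
- Units are analyzed separately; no pooling or mixed-effects structure.
- The race covariate is a single binary minority indicator.
- Wilcoxon pairing is per resident; alternative pairing grains (e.g.
  per resident-week) are not implemented.
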