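# tc-hierarchy

Inference of peer-feedback hierarchies in therapeutic communities (TCs)
from longitudinal correction records, and their relation to treatment
graduation.

## The problem

Therapeutic communities are residential mutual-aid programs for
substance abuse and criminal behaviour in which residents monitor one
another and deliver structured written feedback ("corrections",
sometimes called pull-ups). Each correction is a dated, directed event —
sender → receiver — so over time a unit's corrections form a
longitudinal directed social network. Because the relation is negatively
valenced, network centrality inverts the usual status reading: a
resident corrected by peers who are themselves heavily corrected sits
*low* in the unit's dominance hierarchy, exactly as the most-pecked bird
sits at the bottom of a pecking order. This package asks two clinical
questions of such data:

1. **Do residents climb the hierarchy over their stay?** (their
   last-month centrality should be lower than their whole-stay
   centrality), and
2. **Does hierarchy position predict graduation?** (the program's key
   proximal outcome).

## The method

For a unit observed over a span of days the pipeline:

1. tiles the span with contiguous one-week windows (weekly aggregation
   removes day-of-week periodicity) and builds, per window, the weighted
   directed correction network over every resident present that week;
2. scores each week's residents with eigenvector centrality in in-edge
   form on the perturbed matrix

   *M* = *W*ᵀ + ε*J*,

   where *W* is the weekly weight matrix, *J* the all-ones matrix and
   ε > 0 a small teleport floor. Weekly correction graphs are sparse,
   reducible and often acyclic, on which the unperturbed leading
   eigenvector is degenerate or identically zero; for any ε > 0, *M* is
   primitive, so the Perron–Frobenius eigenvector is unique and strictly
   positive. Scores are max-normalized (largest score = 1);
3. assembles each resident's weekly trajectory and summarizes it into
   four hierarchy measures: **Maximum** and **Mean Eigenvector
   Centrality** over the whole stay, and the same two over the final
   four weeks (**Last Month Maximum / Mean**);
4. tests the climb hypothesis with Wilcoxon signed-rank tests (tie- and
   continuity-corrected normal approximation, matching
   `wilcox.test(..., paired=TRUE, correct=TRUE)`) pairing each
   resident's overall measure with their last-month measure; and
5. fits four logistic regressions of graduation — one per hierarchy
   measure — controlling for age, LSI-R recidivism-risk score, a
   minority-race indicator and days in program, reporting Wald
   inference, log-likelihood, deviance, AIC and BIC, plus
   predicted-probability curves over each measure's range.

Clinical correction databases are not generally shareable, so the
package includes a synthetic TC-unit generator (bed-limited Poisson
arrivals, truncated-normal tenures, a latent-rank random walk driving
down-rank correction flow, and graduation linked to final rank) that
reproduces the statistical structure the analysis assumes and gives
ground truth for recovery tests.

## Worked example

```python
from tc_hierarchy import TCHierarchy, SimulationConfig, simulate_unit

roster, events, truth = simulate_unit(SimulationConfig(seed=1))
results = TCHierarchy(events, roster).fit()   # or TCHierarchy.from_csv(...)
print(results.summary())
```

prints (abridged):

```
N (complete residents): 350

Descriptives
------------------------------------------------------------
Graduation                                    0.797
Days in Program                             120.126 (41.713)
Maximum Eigenvector Centrality                0.623 (0.338)
Last Month Maximum Eigenvector Centrality     0.095 (0.203)
Mean Eigenvector Centrality                   0.081 (0.064)
Last Month Mean Eigenvector Centrality        0.029 (0.060)

Hierarchy climb (overall vs last month, signed rank)
------------------------------------------------------------
Maximum EC   V = 49770, z = 15.382, p = 2.15e-53 (n = 315 nonzero pairs)
Mean EC      V = 53453, z = 13.490, p = 1.8e-41 (n = 340 nonzero pairs)
```

Reading the output: the unit graduates ~80% of its residents after ~120
days on average. Last-month centralities (0.095 / 0.029) sit well below
whole-stay centralities (0.623 / 0.081) and the signed-rank tests reject
decisively — residents systematically climb the hierarchy over their
stay. The model table (four logistic fits sharing n and covariates)
carries the graduation coefficients; with the generator's default mild
hierarchy→graduation effect the four hierarchy coefficients here are all
negative but individually small. Curves come from
`results.predict_graduation_curve("max_ec")` and
`results.plot_predicted_probability()`.

A command-line interface mirrors the library:

```bash
tc-hierarchy simulate --seed 1 --out simdir
tc-hierarchy validate --events simdir/corrections.csv --roster simdir/roster.csv
tc-hierarchy run --config pipeline.yaml
tc-hierarchy report rundir
```

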