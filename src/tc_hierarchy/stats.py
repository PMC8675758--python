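"""Inferential stage: signed-rank tests of hierarchy climb and logistic
regressions of graduation on hierarchy position.

Two questions are asked of every unit.  First, do residents climb the
hierarchy — are last-month centrality measures lower than whole-stay
measures?  This is a paired comparison per resident, tested with the
Wilcoxon signed-rank test using the tie-corrected normal approximation
with a 0.5 continuity correction (zero differences are dropped before
ranking, Wilcoxon's original convention).  Second, does hierarchy
position predict graduation?  Four logistic regressions — one per
hierarchy measure, sharing the covariates age, LSI-R, race indicator and
days in program — model the graduation outcome; coefficients carry Wald
standard errors and p-values, and each fit reports log-likelihood,
deviance (−2ℓ), AIC (−2ℓ + 2k) and BIC (−2ℓ + k·ln n).

The logistic fits are maximum-likelihood via IRLS (statsmodels'
``Logit``); the signed-rank machinery is implemented here because the
reporting requires V, z and the tie/continuity corrections as explicit
fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .measures import MEASURE_LABELS

COVARIATES = ["age", "lsi_r", "race_minority", "days_in_program"]
COVARIATE_LABELS = {
    "intercept": "Intercept",
    "age": "Age",
    "lsi_r": "LSI-R",
    "race_minority": "Race",
    "days_in_program": "Days in Program",
}


@dataclass
class WilcoxonResult:
    """Signed-rank test summary (V, z and two-sided/one-sided p)."""

    V: float
    p_value: float
    n_pairs: int
    n_nonzero: int
    z: float


@dataclass
class LogisticFit:
    """One logistic model: per-term (beta, se, p) plus fit statistics."""

    coefficients: dict[str, tuple[float, float, float]]
    log_likelihood: float
    deviance: float
    aic: float
    bic: float
    n: int
    converged: bool

    def beta(self, term: str) -> float:
        return self.coefficients[term][0]

    def se(self, term: str) -> float:
        return self.coefficients[term][1]

    def p(self, term: str) -> float:
        return self.coefficients[term][2]


@dataclass
class UnitResults:
    """All inferential output for one unit.

    The four models share outcome, covariates and n; they differ only in
    which hierarchy measure enters.  ``models`` values may be ``None``
    (with an explanatory entry in ``notes``) when a model is undefined,
    e.g. a measure without variation.
    """

    descriptives: pd.DataFrame
    wilcoxon_max: WilcoxonResult | None
    wilcoxon_mean: WilcoxonResult | None
    models: dict[str, LogisticFit | None]
    n: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _wc(w):
            if w is None:
                return None
            return {
                "V": w.V,
                "p_value": w.p_value,
                "n_pairs": w.n_pairs,
                "n_nonzero": w.n_nonzero,
                "z": w.z,
            }

        def _fit(f):
            if f is None:
                return None
            return {
                "coefficients": {
                    t: {"beta": b, "se": s, "p": p}
                    for t, (b, s, p) in f.coefficients.items()
                },
                "log_likelihood": f.log_likelihood,
                "deviance": f.deviance,
                "aic": f.aic,
                "bic": f.bic,
                "n": f.n,
                "converged": f.converged,
            }

        return {
            "n": self.n,
            "descriptives": {
                str(r.variable): {
                    "statistic": r.statistic,
                    "value": r.value,
                    "sd": None if pd.isna(r.sd) else r.sd,
                }
                for r in self.descriptives.itertuples(index=False)
            },
            "wilcoxon_max": _wc(self.wilcoxon_max),
            "wilcoxon_mean": _wc(self.wilcoxon_mean),
            "models": {k: _fit(v) for k, v in self.models.items()},
            "notes": list(self.notes),
        }

    def summary(self) -> str:
        """Plain-text report: descriptives, signed-rank tests, model table."""
        out = ["Unit analysis", "=" * 60, "", f"N (complete residents): {self.n}", ""]
        out.append("Descriptives")
        out.append("-" * 60)
        for r in self.descriptives.itertuples(index=False):
            if pd.isna(r.sd):
                out.append(f"{r.variable:<42s} {r.value:8.3f}")
            else:
                out.append(f"{r.variable:<42s} {r.value:8.3f} ({r.sd:.3f})")
        out.append("")
        out.append("Hierarchy climb (overall vs last month, signed rank)")
        out.append("-" * 60)
        for label, w in (
            ("Maximum EC", self.wilcoxon_max),
            ("Mean EC", self.wilcoxon_mean),
        ):
            if w is None:
                out.append(f"{label:<12s} no hierarchy movement")
            else:
                out.append(
                    f"{label:<12s} V = {w.V:.0f}, z = {w.z:.3f}, "
                    f"p = {w.p_value:.3g} (n = {w.n_nonzero} nonzero pairs)"
                )
        out.append("")
        out.append("Graduation models (logistic; Wald SE in parentheses)")
        out.append("-" * 60)
        terms = ["intercept"] + COVARIATES
        headers = [f"Model {i + 1}" for i in range(len(self.models))]
        out.append(f"{'':<42s}" + "".join(f"{h:>16s}" for h in headers))
        fits = list(self.models.values())

        def _cell(fit, term):
            if fit is None or term not in fit.coefficients:
                return f"{'':>16s}"
            b, s, p = fit.coefficients[term]
            return f"{b:>10.2f}{_stars(p):<3s}   "

        for term in terms:
            out.append(
                f"{COVARIATE_LABELS[term]:<42s}"
                + "".join(_cell(f, term) for f in fits)
            )
        for meas in self.models:
            out.append(
                f"{MEASURE_LABELS[meas]:<42s}"
                + "".join(_cell(f, meas) for f in fits)
            )
        for stat, attr in (
            ("AIC", "aic"),
            ("BIC", "bic"),
            ("Log-Likelihood", "log_likelihood"),
            ("Deviance", "deviance"),
            ("N", "n"),
        ):
            row = f"{stat:<42s}"
            for f in fits:
                if f is None:
                    row += f"{'':>16s}"
                elif stat == "N":
                    row += f"{f.n:>12d}    "
                else:
                    row += f"{getattr(f, attr):>12.2f}    "
            out.append(row)
        out.append("")
        out.append("*** p < 0.001, ** p < 0.01, * p < 0.05")
        if self.notes:
            out.append("")
            out.append("Notes: " + "; ".join(self.notes))
        return "\n".join(out) + "\n"


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test with continuity correction.

    Differences ``d = x - y``; zero differences are dropped, |d| is
    ranked with average ranks for ties, and ``V`` is the sum of ranks of
    positive differences.  The p-value uses the normal approximation with
    tie-corrected variance and a 0.5 continuity correction toward the
    null mean.

    Raises ``ValueError`` when all differences are zero (the test is
    undefined: there is no movement to rank).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-d samples")
    d = x - y
    d_nz = d[d != 0]
    if d_nz.size == 0:
        raise ValueError("undefined: no nonzero differences")
    n = d_nz.size
    ranks = sps.rankdata(np.abs(d_nz))
    v = float(ranks[d_nz > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d_nz), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts).sum())
    ) / 48.0
    z0 = v - mu
    if alternative == "two-sided":
        correction = 0.5 * np.sign(z0)
    elif alternative == "greater":
        correction = 0.5
    elif alternative == "less":
        correction = -0.5
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    z = (z0 - correction) / np.sqrt(sigma2)
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return WilcoxonResult(
        V=v,
        p_value=float(min(p, 1.0)),
        n_pairs=int(x.size),
        n_nonzero=int(n),
        z=float(z),
    )


def fit_logistic(
    outcome: Sequence[int], design: pd.DataFrame
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``design`` columns are the model terms (include an ``intercept``
    column of ones explicitly).  Detected separation (Newton failure, or
    a coefficient beyond ±15) flags the fit non-converged; estimates are
    still reported.
    """
    y = np.asarray(outcome, dtype=float)
    x = design.to_numpy(dtype=float)
    n, k = x.shape
    if n <= k:
        raise ValueError("need more observations than model terms")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; model undefined")
    model = sm.Logit(y, x)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="newton", maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="bfgs", maxiter=500)
        converged = False
    if np.max(np.abs(res.params)) > 15:
        converged = False
    if not converged:
        warnings.warn(
            "logistic fit flagged non-converged (possible separation); "
            "estimates reported anyway",
            RuntimeWarning,
        )
    llf = float(res.llf)
    deviance = -2.0 * llf
    coeffs = {
        term: (float(b), float(s), float(p))
        for term, b, s, p in zip(design.columns, res.params, res.bse, res.pvalues)
    }
    return LogisticFit(
        coefficients=coeffs,
        log_likelihood=llf,
        deviance=deviance,
        aic=deviance + 2 * k,
        bic=deviance + k * np.log(n),
        n=int(n),
        converged=converged,
    )


def logistic_log_likelihood(
    beta: np.ndarray, y: np.ndarray, x: np.ndarray
) -> float:
    """Bernoulli log-likelihood ℓ(β) = Σ yᵢη − log(1 + exp η), η = xβ."""
    eta = x @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_score(beta: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Score (gradient of ℓ): Xᵀ(y − p)."""
    p = 1.0 / (1.0 + np.exp(-(x @ beta)))
    return x.T @ (y - p)


def _descriptives(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var, label, kind in (
        ("graduated", "Graduation", "proportion"),
        ("age", "Age", "mean"),
        ("lsi_r", "LSI-R", "mean"),
        ("race_minority", "Race (minority proportion)", "proportion"),
        ("days_in_program", "Days in Program", "mean"),
        ("max_ec", MEASURE_LABELS["max_ec"], "mean"),
        ("lm_max_ec", MEASURE_LABELS["lm_max_ec"], "mean"),
        ("mean_ec", MEASURE_LABELS["mean_ec"], "mean"),
        ("lm_mean_ec", MEASURE_LABELS["lm_mean_ec"], "mean"),
    ):
        vals = df[var].astype(float)
        if kind == "proportion":
            rows.append((label, "proportion", float(vals.mean()), np.nan))
        else:
            rows.append((label, "mean", float(vals.mean()), float(vals.std(ddof=1))))
    return pd.DataFrame(rows, columns=["variable", "statistic", "value", "sd"])


def run_unit_analysis(
    summaries: pd.DataFrame,
    roster: pd.DataFrame,
    small_sample_threshold: int = 20,
) -> UnitResults:
    """Full inferential stage for one unit.

    Joins the hierarchy-summary table to the roster, excludes residents
    with incomplete covariates, computes descriptives, both signed-rank
    climb tests and the four graduation models (Model 1 = last-month
    maximum, 2 = last-month mean, 3 = overall maximum, 4 = overall mean).
    """
    roster_cols = [
        "resident_id",
        "graduated",
        "age",
        "lsi_r",
        "race_minority",
        "days_in_program",
        "complete",
    ]
    df = summaries.merge(roster[roster_cols], on="resident_id", how="inner")
    notes: list[str] = []
    n_incomplete = int((~df["complete"]).sum())
    if n_incomplete:
        notes.append(f"{n_incomplete} resident(s) excluded (incomplete covariates)")
    df = df[df["complete"]].reset_index(drop=True)
    n = len(df)
    if n < small_sample_threshold:
        notes.append(
            f"small sample (n = {n} < {small_sample_threshold}); "
            "estimates may be unstable"
        )

    descriptives = _descriptives(df)

    def _climb(overall: str, lastmonth: str, label: str):
        try:
            return wilcoxon_signed_rank(df[overall], df[lastmonth])
        except ValueError:
            notes.append(f"no hierarchy movement ({label} measure)")
            return None

    wc_max = _climb("max_ec", "lm_max_ec", "maximum")
    wc_mean = _climb("mean_ec", "lm_mean_ec", "mean")

    models: dict[str, LogisticFit | None] = {}
    for meas in MEASURE_LABELS:
        if df[meas].astype(float).std(ddof=0) == 0:
            notes.append(f"no variation in {meas}; model skipped")
            models[meas] = None
            continue
        design = pd.DataFrame({"intercept": np.ones(n)})
        for c in COVARIATES:
            design[c] = df[c].astype(float).to_numpy()
        design[meas] = df[meas].astype(float).to_numpy()
        try:
            models[meas] = fit_logistic(df["graduated"].to_numpy(), design)
        except ValueError as exc:
            notes.append(f"model for {meas} undefined: {exc}")
            models[meas] = None

    return UnitResults(
        descriptives=descriptives,
        wilcoxon_max=wc_max,
        wilcoxon_mean=wc_mean,
        models=models,
        n=n,
        notes=notes,
    )


def predicted_probability_curve(
    fit: LogisticFit,
    measure_name: str,
    grid: Sequence[float],
    covariate_profile: Mapping[str, float],
    observed_max: float | None = None,
) -> list[tuple[float, float]]:
    """Graduation probability along a hierarchy-measure grid.

    Other terms are held at ``covariate_profile`` (typically sample means
    for continuous covariates and modes for binary ones).  Grid values
    beyond twice the observed maximum trigger a warning but are still
    evaluated.
    """
    if measure_name not in fit.coefficients:
        raise ValueError(f"{measure_name!r} is not a term of this fit")
    base = fit.beta("intercept") if "intercept" in fit.coefficients else 0.0
    for term, value in covariate_profile.items():
        if term in (measure_name, "intercept"):
            continue
        base += fit.beta(term) * value
    b = fit.beta(measure_name)
    curve = []
    for g in grid:
        if observed_max is not None and g > 2 * observed_max:
            warnings.warn(
                f"grid value {g} far outside observed range "
                f"(max {observed_max})",
                RuntimeWarning,
            )
        eta = base + b * g
        curve.append((float(g), float(1.0 / (1.0 + np.exp(-eta)))))
    return curve
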