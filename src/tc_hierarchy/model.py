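"""Model/Results front-end tying the pipeline stages together.

:class:`TCHierarchy` is built from a corrections table and a roster (as
analysis DataFrames, record lists or CSV paths); ``fit()`` runs weekly
network construction, ε-perturbed eigenvector centrality, trajectory
summarization and the inferential stage, returning a
:class:`TCHierarchyResults` that carries every intermediate table, the
test results and the four logistic fits, with ``summary()``,
predicted-probability curves and plotting attached.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import records as rec
from .centrality import CentralityScores, eigenvector_centrality
from .measures import (
    MEASURE_LABELS,
    build_trajectories,
    summaries_to_frame,
    summarize_hierarchy,
)
from .networks import (
    build_weekly_networks,
    make_week_windows,
    networks_to_edge_frame,
)
from .stats import (
    UnitResults,
    predicted_probability_curve,
    run_unit_analysis,
)


class TCHierarchy:
    """Hierarchy-inference model for one therapeutic-community unit.

    Parameters
    ----------
    events : DataFrame or list of CorrectionEvent
        Validated correction events (columns ``date`` [datetime64],
        ``sender_id``, ``receiver_id``).
    roster : DataFrame or list of ResidentRecord
        Resident roster (analysis-frame columns as produced by
        :func:`tc_hierarchy.records.roster_to_frame`).
    epsilon, tol, max_iter :
        Centrality parameters (perturbation floor, power-iteration
        stopping tolerance and iteration cap).
    binary_edges : bool
        Collapse repeated same-pair weekly corrections to weight 1.
    min_weeks : int
        Exclude residents observed fewer than this many weeks from the
        inferential stage (sensitivity knob; default keeps everyone).
    """

    def __init__(
        self,
        events,
        roster,
        *,
        epsilon: float = 1e-4,
        tol: float = 1e-10,
        max_iter: int = 10_000,
        binary_edges: bool = False,
        min_weeks: int = 1,
    ):
        if not isinstance(events, pd.DataFrame):
            events = rec.events_to_frame(events)
        if not isinstance(roster, pd.DataFrame):
            roster = rec.roster_to_frame(roster)
        if roster.empty:
            raise ValueError("roster is empty")
        self.events = events.reset_index(drop=True)
        self.roster = roster.reset_index(drop=True)
        self.epsilon = float(epsilon)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.binary_edges = bool(binary_edges)
        self.min_weeks = int(min_weeks)
        self.validation_report: rec.ValidationReport | None = None

    @classmethod
    def from_csv(
        cls,
        events_path,
        roster_path,
        events_dialect: Mapping[str, str] | None = None,
        roster_dialect: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "TCHierarchy":
        """Read, validate and cross-validate the two CSV inputs."""
        events, drops = rec.read_corrections(events_path, events_dialect)
        roster = rec.read_roster(roster_path, roster_dialect)
        valid, report = rec.cross_validate(events, roster, drops)
        obj = cls(
            rec.events_to_frame(valid), rec.roster_to_frame(roster), **kwargs
        )
        obj.validation_report = report
        return obj

    def fit(self) -> "TCHierarchyResults":
        """Run the full pipeline and return the results object."""
        span_start = self.roster["entry_date"].min()
        span_end = self.roster["exit_date"].max()
        windows = make_week_windows(span_start, span_end)
        networks = build_weekly_networks(
            self.events, self.roster, windows, binary_edges=self.binary_edges
        )
        weekly_scores = [
            eigenvector_centrality(
                net, epsilon=self.epsilon, tol=self.tol, max_iter=self.max_iter
            )
            for net in networks
        ]
        trajectories = build_trajectories(
            weekly_scores, rec.frame_to_roster(self.roster)
        )
        summaries = [summarize_hierarchy(t) for t in trajectories]
        summary_frame = summaries_to_frame(summaries)
        analysis_frame = summary_frame[
            summary_frame["n_weeks"] >= self.min_weeks
        ].reset_index(drop=True)
        unit_results = run_unit_analysis(analysis_frame, self.roster)
        return TCHierarchyResults(
            model=self,
            windows=windows,
            networks=networks,
            weekly_scores=weekly_scores,
            trajectories=trajectories,
            hierarchy_summaries=summary_frame,
            unit_results=unit_results,
        )


class TCHierarchyResults:
    """Fitted pipeline output for one unit.

    Attributes
    ----------
    networks : list of WeeklyNetwork
    weekly_scores : list of CentralityScores
    hierarchy_summaries : DataFrame
        Per-resident four-measure table (the analysis-ready dataset).
    unit_results : UnitResults
        Descriptives, both signed-rank climb tests and the four
        graduation models.
    """

    def __init__(
        self,
        model: TCHierarchy,
        windows,
        networks,
        weekly_scores: list[CentralityScores],
        trajectories,
        hierarchy_summaries: pd.DataFrame,
        unit_results: UnitResults,
    ):
        self.model = model
        self.windows = windows
        self.networks = networks
        self.weekly_scores = weekly_scores
        self.trajectories = trajectories
        self.hierarchy_summaries = hierarchy_summaries
        self.unit_results = unit_results

    # -- delegation ----------------------------------------------------
    @property
    def wilcoxon_max(self):
        return self.unit_results.wilcoxon_max

    @property
    def wilcoxon_mean(self):
        return self.unit_results.wilcoxon_mean

    @property
    def models(self):
        return self.unit_results.models

    @property
    def n(self) -> int:
        return self.unit_results.n

    def summary(self) -> str:
        return self.unit_results.summary()

    def to_dict(self) -> dict:
        return self.unit_results.to_dict()

    # -- tables ---------------------------------------------------------
    def centrality_table(self) -> pd.DataFrame:
        """Long table (window_index, resident_id, score) over all weeks."""
        rows = []
        for cs in self.weekly_scores:
            for rid, score in sorted(cs.scores.items()):
                rows.append((cs.window.index, rid, score))
        return pd.DataFrame(
            rows, columns=["window_index", "resident_id", "score"]
        )

    def edge_table(self) -> pd.DataFrame:
        return networks_to_edge_frame(self.networks)

    # -- prediction and plotting ----------------------------------------
    def _analysis_frame(self) -> pd.DataFrame:
        df = self.hierarchy_summaries.merge(
            self.model.roster, on="resident_id", how="inner"
        )
        return df[df["complete"]]

    def covariate_profile(self) -> dict[str, float]:
        """Sample means for continuous covariates, mode for the binary one."""
        df = self._analysis_frame()
        profile = {
            c: float(df[c].astype(float).mean())
            for c in ("age", "lsi_r", "days_in_program")
        }
        profile["race_minority"] = float(
            df["race_minority"].astype(float).round().mode().iloc[0]
        )
        return profile

    def predict_graduation_curve(
        self,
        measure: str,
        grid: Sequence[float] | None = None,
        profile: Mapping[str, float] | None = None,
    ) -> list[tuple[float, float]]:
        """Predicted graduation probability along one measure's range."""
        fit = self.models[measure]
        if fit is None or not fit.converged:
            raise ValueError(f"model for {measure!r} unavailable or not converged")
        df = self._analysis_frame()
        observed_max = float(df[measure].max())
        if grid is None:
            grid = np.linspace(0.0, observed_max, 50)
        if profile is None:
            profile = self.covariate_profile()
        return predicted_probability_curve(
            fit, measure, list(grid), profile, observed_max=observed_max
        )

    def plot_predicted_probability(
        self, measures: Sequence[str] = ("max_ec", "lm_max_ec"), ax=None
    ):
        """Predicted-probability curves per measure on one axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for meas in measures:
            curve = self.predict_graduation_curve(meas)
            xs, ys = zip(*curve)
            ax.plot(xs, ys, label=MEASURE_LABELS[meas])
        ax.set_xlabel("eigenvector centrality")
        ax.set_ylabel("predicted probability of graduation")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=8)
        return ax
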