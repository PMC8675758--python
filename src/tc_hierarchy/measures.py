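"""Per-resident centrality trajectories and the four hierarchy measures.

A resident's trajectory is their weekly centrality score over every week
their tenure overlaps.  Four summaries describe their path through the
hierarchy: the maximum and mean score over the whole stay, and the
maximum and mean over the final four weeks ("last month").  Because
scores are negatively valenced (high score = low hierarchy position),
lower last-month values than overall values indicate a rise in the
hierarchy over the course of treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .centrality import CentralityScores
from .records import ResidentRecord

#: analysis-frame column, display label — in the reporting order Model 1..4
MEASURE_LABELS = {
    "lm_max_ec": "Last Month Maximum Eigenvector Centrality",
    "lm_mean_ec": "Last Month Mean Eigenvector Centrality",
    "max_ec": "Maximum Eigenvector Centrality",
    "mean_ec": "Mean Eigenvector Centrality",
}


@dataclass
class CentralityTrajectory:
    """Ordered (window index, score) points over one resident's tenure."""

    resident_id: str
    points: list[tuple[int, float]]

    @property
    def n_weeks(self) -> int:
        return len(self.points)

    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.points])


@dataclass
class HierarchySummary:
    """The four hierarchy measures for one resident."""

    resident_id: str
    max_ec: float
    mean_ec: float
    lm_max_ec: float
    lm_mean_ec: float
    n_weeks: int
    n_lm_weeks: int


def build_trajectories(
    weekly_scores: Iterable[CentralityScores],
    roster: Sequence[ResidentRecord] | pd.DataFrame,
) -> list[CentralityTrajectory]:
    """Assemble one trajectory per resident from per-window score maps.

    Input order of ``weekly_scores`` is irrelevant (windows are keyed by
    index).  Residents appearing in no window are excluded with a warning.
    """
    by_window = {cs.window.index: cs for cs in weekly_scores}
    if isinstance(roster, pd.DataFrame):
        ids = [str(r) for r in roster["resident_id"]]
    else:
        ids = [r.resident_id for r in roster]
    trajectories = []
    ordered = sorted(by_window.items())
    for rid in ids:
        points = [
            (k, cs.scores[rid]) for k, cs in ordered if rid in cs.scores
        ]
        if not points:
            warnings.warn(
                f"resident {rid!r} overlaps no scored window; excluded",
                RuntimeWarning,
            )
            continue
        trajectories.append(CentralityTrajectory(rid, points))
    return trajectories


def summarize_hierarchy(trajectory: CentralityTrajectory) -> HierarchySummary:
    """Compute the four measures; "last month" = final min(4, n) weeks."""
    if not trajectory.points:
        raise ValueError("empty trajectory")
    s = trajectory.scores()
    n_lm = min(4, s.size)
    lm = s[-n_lm:]
    return HierarchySummary(
        resident_id=trajectory.resident_id,
        max_ec=float(s.max()),
        mean_ec=float(s.mean()),
        lm_max_ec=float(lm.max()),
        lm_mean_ec=float(lm.mean()),
        n_weeks=int(s.size),
        n_lm_weeks=int(n_lm),
    )


def paired_measures(
    summaries: Sequence[HierarchySummary],
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Per-resident (overall, last-month) pairs for the signed-rank stage.

    Returns the maximum-measure pairs and the mean-measure pairs, in
    input (roster) order.
    """
    max_pairs = [(s.max_ec, s.lm_max_ec) for s in summaries]
    mean_pairs = [(s.mean_ec, s.lm_mean_ec) for s in summaries]
    return max_pairs, mean_pairs


def summaries_to_frame(summaries: Sequence[HierarchySummary]) -> pd.DataFrame:
    """Analysis-ready per-resident table of the four measures."""
    return pd.DataFrame(
        {
            "resident_id": [s.resident_id for s in summaries],
            "max_ec": [s.max_ec for s in summaries],
            "mean_ec": [s.mean_ec for s in summaries],
            "lm_max_ec": [s.lm_max_ec for s in summaries],
            "lm_mean_ec": [s.lm_mean_ec for s in summaries],
            "n_weeks": [s.n_weeks for s in summaries],
            "n_lm_weeks": [s.n_lm_weeks for s in summaries],
        }
    )
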