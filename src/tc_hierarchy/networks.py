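"""Weekly aggregation of correction events into weighted directed networks.

The observation span is tiled with contiguous half-open one-week windows
(weekly aggregation removes day-of-week periodicity in correction
activity).  Each window yields one :class:`WeeklyNetwork`: nodes are all
residents whose tenure overlaps the window — including residents who gave
and received no corrections that week, so that every resident has a
defined centrality for every week of their stay — and the integer weight
``W[s, r]`` counts the corrections sender ``s`` gave receiver ``r``
within the window.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeekWindow:
    """Half-open seven-day window ``[start, end)``."""

    index: int
    start: datetime.date
    end: datetime.date

    def __post_init__(self) -> None:
        if (self.end - self.start).days != 7:
            raise ValueError("window must span exactly 7 days")


@dataclass
class WeeklyNetwork:
    """One week's directed correction network.

    ``weights`` is a dense square nonnegative integer matrix aligned with
    ``nodes``; the diagonal is structurally zero (self-corrections are
    rejected upstream).
    """

    window: WeekWindow
    nodes: list[str]
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())

    def to_digraph(self):
        """Export as a :class:`networkx.DiGraph` with ``weight`` edge data."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        senders, receivers = np.nonzero(self.weights)
        for s, r in zip(senders, receivers):
            g.add_edge(
                self.nodes[s], self.nodes[r], weight=int(self.weights[s, r])
            )
        return g


def make_week_windows(
    span_start: datetime.date, span_end: datetime.date
) -> list[WeekWindow]:
    """Tile ``[span_start, span_end]`` (inclusive) with one-week windows.

    Window ``k`` covers ``[span_start + 7k, span_start + 7(k+1))``; the
    last window may extend past ``span_end`` so the tiling always covers
    the full span.
    """
    span_start = _as_date(span_start)
    span_end = _as_date(span_end)
    if span_end < span_start:
        raise ValueError("span_end precedes span_start")
    n_days = (span_end - span_start).days + 1
    n_windows = -(-n_days // 7)  # ceil
    return [
        WeekWindow(
            k,
            span_start + datetime.timedelta(days=7 * k),
            span_start + datetime.timedelta(days=7 * (k + 1)),
        )
        for k in range(n_windows)
    ]


def _as_date(d) -> datetime.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    return d


def present_mask(roster: pd.DataFrame, window: WeekWindow) -> np.ndarray:
    """Boolean mask of roster rows whose tenure intersects the window.

    Tenure is the closed interval ``[entry_date, exit_date]``; it
    intersects the half-open window iff ``entry < end`` and
    ``exit >= start``.
    """
    start = pd.Timestamp(window.start)
    end = pd.Timestamp(window.end)
    return (
        (roster["entry_date"] < end) & (roster["exit_date"] >= start)
    ).to_numpy()


def build_weekly_network(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    window: WeekWindow,
    binary_edges: bool = False,
) -> WeeklyNetwork:
    """Build the correction network for one window.

    ``events`` must already be cross-validated against ``roster``: an
    in-window event naming a resident not present that week raises
    ``RuntimeError`` (it indicates validation was skipped).

    With ``binary_edges=True`` repeated same-pair corrections within the
    week collapse to weight 1 (sensitivity variant); by default they
    accumulate as integer weight.
    """
    nodes = sorted(roster.loc[present_mask(roster, window), "resident_id"])
    index = {rid: i for i, rid in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
    start, end = pd.Timestamp(window.start), pd.Timestamp(window.end)
    in_window = events[(events["date"] >= start) & (events["date"] < end)]
    for row in in_window.itertuples(index=False):
        try:
            s, r = index[row.sender_id], index[row.receiver_id]
        except KeyError as exc:
            raise RuntimeError(
                f"event in window {window.index} references resident "
                f"{exc.args[0]!r} not present that week; run cross_validate first"
            ) from None
        w[s, r] += 1
    if binary_edges:
        w = (w > 0).astype(np.int64)
    return WeeklyNetwork(window, nodes, w)


def build_weekly_networks(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    windows: list[WeekWindow],
    binary_edges: bool = False,
) -> list[WeeklyNetwork]:
    """Build one :class:`WeeklyNetwork` per window (see single-window form)."""
    return [
        build_weekly_network(events, roster, win, binary_edges=binary_edges)
        for win in windows
    ]


def networks_to_edge_frame(networks: list[WeeklyNetwork]) -> pd.DataFrame:
    """Flatten networks to an edge-list table for export/inspection."""
    rows = []
    for net in networks:
        senders, receivers = np.nonzero(net.weights)
        for s, r in zip(senders, receivers):
            rows.append(
                (
                    net.window.index,
                    net.nodes[s],
                    net.nodes[r],
                    int(net.weights[s, r]),
                )
            )
    return pd.DataFrame(
        rows, columns=["window_index", "sender_id", "receiver_id", "weight"]
    )
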