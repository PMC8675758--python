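"""Synthetic therapeutic-community unit generator.

The real clinical correction databases are not publicly deposited, so the
pipeline is exercised on a generative stand-in that reproduces the
statistical structure the analysis assumes:

* **Occupancy** — Poisson daily arrivals thinned by bed availability;
  occupancy never exceeds ``n_beds``.
* **Tenure** — truncated-normal lengths of stay (default mean 135 days,
  sd 35, minimum 14), clipped at the end of observation.
* **Latent hierarchy** — each resident carries a latent rank that starts
  at 0 on entry (new entrants are lowest-ranked) and performs a drifting
  random walk: + ``rank_growth_rate`` per week plus Gaussian noise.
* **Corrections** — each week, ordered co-present pairs (s, v) generate
  Poisson counts with mean proportional to a logistic preference
  σ((rank_s − rank_v)/temperature), so corrections flow predominantly
  down-rank; the total is scaled to ``corrections_per_resident_week``
  expected corrections per present resident.
* **Graduation** — Bernoulli with logit = ``grad_intercept`` +
  ``grad_rank_coef`` × (standardized final rank) + ``grad_lsi_coef`` ×
  (LSI-R − 26).  With positive ``grad_rank_coef``, residents who climb
  the hierarchy graduate more often — the effect the pipeline should
  recover as *negative* centrality coefficients.
* **Covariates** — age ~ N(29, 8.6) truncated ≥ 18; LSI-R ~ N(26, 7)
  truncated ≥ 0, rounded; minority indicator ~ Bernoulli(0.2) — matching
  the covariate scale of the real units' descriptive tables.

All randomness flows from the single config seed; identical configs
yield byte-identical roster/event CSVs.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic TC unit.

    Defaults describe a large men's-unit-like facility: 80 beds observed
    for 604 days (a realistic span matching the shortest-observed real
    unit), near-capacity occupancy, ~19-week mean stays and a graduation
    rate around 0.8.
    """

    n_beds: int = 80
    arrival_rate: float = 0.7  # expected arrivals/day before bed thinning
    mean_tenure_days: float = 135.0
    tenure_sd_days: float = 35.0
    min_tenure_days: float = 14.0
    corrections_per_resident_week: float = 1.5
    rank_growth_rate: float = 0.5  # latent rank drift per week present
    rank_noise_sd: float = 0.8  # weekly random-walk innovation sd
    rank_preference_temperature: float = 1.0
    grad_intercept: float = 1.9
    grad_rank_coef: float = 1.0  # per sd of final latent rank
    grad_lsi_coef: float = -0.05  # per LSI-R point (centered at 26)
    span_days: int = 604
    seed: int = 0
    start_date: datetime.date = field(
        default_factory=lambda: datetime.date(2015, 1, 5)
    )

    def validate(self) -> None:
        if self.n_beds < 1:
            raise ValueError("n_beds must be >= 1")
        if self.span_days < 14:
            raise ValueError("span_days must be >= 14")
        for name in (
            "arrival_rate",
            "corrections_per_resident_week",
            "tenure_sd_days",
            "rank_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_tenure_days <= 0 or self.min_tenure_days <= 0:
            raise ValueError("tenure parameters must be positive")
        if self.rank_preference_temperature <= 0:
            raise ValueError("rank_preference_temperature must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = datetime.date.fromisoformat(d["start_date"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery tests."""

    final_rank: dict[str, float]
    rank_trajectory: dict[str, list[tuple[int, float]]]
    graduation_probability: dict[str, float]
    config: SimulationConfig

    def to_dict(self) -> dict:
        return {
            "final_rank": self.final_rank,
            "rank_trajectory": {
                k: [[int(w), float(r)] for w, r in v]
                for k, v in self.rank_trajectory.items()
            },
            "graduation_probability": self.graduation_probability,
            "config": self.config.to_dict(),
        }


def _truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                             random_state=rng)


def simulate_unit(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one unit; returns (roster frame, events frame, truth).

    The frames use the same columns as the records module's analysis
    frames, so they feed the model directly or can be written to the
    interchange CSVs via :func:`tc_hierarchy.records.write_roster` /
    ``write_corrections``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    span = config.span_days

    # --- arrivals thinned by bed availability -------------------------
    entry_day: list[int] = []
    exit_day: list[int] = []
    active_exits: list[int] = []  # exit days of current occupants
    for day in range(span - 1):
        active_exits = [e for e in active_exits if e >= day]
        n_arrive = rng.poisson(config.arrival_rate)
        free = config.n_beds - len(active_exits)
        for _ in range(min(n_arrive, max(free, 0))):
            tenure = float(
                _truncated_normal(
                    rng,
                    config.mean_tenure_days,
                    config.tenure_sd_days,
                    config.min_tenure_days,
                    1,
                )[0]
            )
            e = min(day + int(round(tenure)), span - 1)
            e = max(e, day + 1)
            entry_day.append(day)
            exit_day.append(e)
            active_exits.append(e)

    n = len(entry_day)
    entry = np.array(entry_day)
    exit_ = np.array(exit_day)
    ids = [f"R{i + 1:04d}" for i in range(n)]

    # --- covariates ---------------------------------------------------
    age = np.round(_truncated_normal(rng, 29.0, 8.6, 18.0, n), 1)
    lsi = np.round(_truncated_normal(rng, 26.0, 7.0, 0.0, n)).astype(int)
    race = rng.binomial(1, 0.2, size=n)

    # --- weekly latent ranks and corrections --------------------------
    n_weeks = -(-span // 7)
    rank = np.zeros(n)
    traj: dict[str, list[tuple[int, float]]] = {rid: [] for rid in ids}
    ev_day: list[int] = []
    ev_sender: list[str] = []
    ev_receiver: list[str] = []
    for w in range(n_weeks):
        w0, w1 = 7 * w, min(7 * w + 6, span - 1)
        present = np.nonzero((entry <= w1) & (exit_ >= w0))[0]
        if present.size == 0:
            continue
        # drifting random walk; entrants joined at rank 0
        rank[present] += config.rank_growth_rate + rng.normal(
            0.0, config.rank_noise_sd, size=present.size
        )
        for i in present:
            traj[ids[i]].append((w, float(rank[i])))
        if present.size < 2 or config.corrections_per_resident_week == 0:
            continue
        r = rank[present]
        diff = r[:, None] - r[None, :]  # sender rank − receiver rank
        pref = 1.0 / (1.0 + np.exp(-diff / config.rank_preference_temperature))
        np.fill_diagonal(pref, 0.0)
        total = config.corrections_per_resident_week * present.size
        lam = total * pref / pref.sum()
        counts = rng.poisson(lam)
        for si, ri in zip(*np.nonzero(counts)):
            s, v = present[si], present[ri]
            lo = max(w0, entry[s], entry[v])
            hi = min(w1, exit_[s], exit_[v])
            if hi < lo:
                continue  # co-present in week but never on the same day
            days = rng.integers(lo, hi + 1, size=counts[si, ri])
            for d in days:
                ev_day.append(int(d))
                ev_sender.append(ids[s])
                ev_receiver.append(ids[v])

    # --- graduation ---------------------------------------------------
    final_rank = rank.copy()
    sd = final_rank.std(ddof=0)
    z = (final_rank - final_rank.mean()) / sd if sd > 0 else np.zeros(n)
    logit = (
        config.grad_intercept
        + config.grad_rank_coef * z
        + config.grad_lsi_coef * (lsi - 26.0)
    )
    p_grad = 1.0 / (1.0 + np.exp(-logit))
    graduated = rng.binomial(1, p_grad)

    # --- assemble frames ----------------------------------------------
    base = pd.Timestamp(config.start_date)
    roster = pd.DataFrame(
        {
            "resident_id": ids,
            "entry_date": base + pd.to_timedelta(entry, unit="D"),
            "exit_date": base + pd.to_timedelta(exit_, unit="D"),
            "graduated": graduated.astype(int),
            "age": age.astype(float),
            "race_minority": race.astype(float),
            "lsi_r": lsi.astype(float),
        }
    )
    roster["days_in_program"] = (exit_ - entry).astype(int)
    roster["complete"] = True
    events = pd.DataFrame(
        {
            "date": base + pd.to_timedelta(ev_day, unit="D"),
            "sender_id": ev_sender,
            "receiver_id": ev_receiver,
        }
    ).sort_values(["date", "sender_id", "receiver_id"], kind="stable")
    events = events.reset_index(drop=True)
    truth = SimTruth(
        final_rank=dict(zip(ids, final_rank.tolist())),
        rank_trajectory=traj,
        graduation_probability=dict(zip(ids, p_grad.tolist())),
        config=config,
    )
    return roster, events, truth


def write_simulation(roster: pd.DataFrame, events: pd.DataFrame,
                     truth: SimTruth, out_dir) -> dict[str, str]:
    """Write roster/corrections CSVs (records-module dialect) + truth JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": str(out / "roster.csv"),
        "corrections": str(out / "corrections.csv"),
        "truth": str(out / "truth.json"),
    }
    r = roster.copy()
    r["entry_date"] = r["entry_date"].dt.strftime("%Y-%m-%d")
    r["exit_date"] = r["exit_date"].dt.strftime("%Y-%m-%d")
    r.drop(columns=["days_in_program", "complete"]).to_csv(
        paths["roster"], index=False
    )
    e = events.copy()
    e["date"] = e["date"].dt.strftime("%Y-%m-%d")
    e.to_csv(paths["corrections"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def replay_determinism(config: SimulationConfig) -> bool:
    """True iff two runs with the same config yield byte-identical files."""
    outputs = []
    for _ in range(2):
        roster, events, _ = simulate_unit(config)
        outputs.append(
            roster.to_csv(index=False) + "\n---\n" + events.to_csv(index=False)
        )
    return outputs[0] == outputs[1]
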