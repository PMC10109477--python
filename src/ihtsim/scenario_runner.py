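"""Replicated scenario experiments and waiting-time aggregation.

``run_experiment`` executes each scenario for a number of replications under
common random numbers: replication ``r`` uses the same derived seed in every
scenario, so policy and load contrasts are paired and their variance is
reduced.  Observations are the waiting times in hours, aggregated either per
request (default), per day, or per (day, period).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .des_engine import TransferRecord, run_replication
from .model_config import ModelConfig, ScenarioConfig
from .stats import GroupSummary

__all__ = [
    "GroupObservations",
    "replication_seed",
    "run_experiment",
    "summarize",
    "summary_table",
]

AggregationLevel = Literal["per_request", "per_day", "per_day_period"]


@dataclass
class GroupObservations:
    """All waiting-time observations (hours) collected for one scenario."""

    scenario_code: str
    observations: list[float]
    aggregation_level: AggregationLevel = "per_request"

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.observations):
            raise ValueError("waiting times must be nonnegative")


def replication_seed(base_seed: int, replication: int) -> int:
    """Deterministic per-replication seed, shared across scenarios (CRN).

    Kept below 2**31 so it is portable as a seed everywhere.
    """
    return int(
        np.random.SeedSequence([base_seed, replication]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _aggregate(
    records: Sequence[TransferRecord],
    level: AggregationLevel,
    shift_of,
) -> list[float]:
    waits = [(r.request_time, r.waiting_minutes / 60.0) for r in records]
    if level == "per_request":
        return [w for _, w in waits]
    if level == "per_day":
        df = pd.DataFrame(waits, columns=["t", "w"])
        df["day"] = (df["t"] // 1440).astype(int)
        return df.groupby("day")["w"].mean().tolist()
    if level == "per_day_period":
        df = pd.DataFrame(waits, columns=["t", "w"])
        df["day"] = (df["t"] // 1440).astype(int)
        df["period"] = [shift_of(t % 1440) for t in df["t"]]
        return df.groupby(["day", "period"])["w"].mean().tolist()
    raise ValueError(f"unknown aggregation level {level!r}")


def run_experiment(
    scenarios: Sequence[ScenarioConfig],
    config: ModelConfig,
    reps: int = 30,
    horizon_days: int = 13,
    base_seed: int = 0,
    *,
    aggregation: AggregationLevel = "per_request",
) -> dict[str, GroupObservations]:
    """Run every scenario for ``reps`` replications of ``horizon_days`` days.

    Returns a map from scenario code to its pooled waiting-time observations.
    Deterministic in ``base_seed``; scenarios share per-replication seeds.
    """
    if reps < 1 or not scenarios:
        raise ValueError("need reps >= 1 and at least one scenario")
    seeds = [replication_seed(base_seed, r) for r in range(reps)]
    out: dict[str, GroupObservations] = {}
    for scen in scenarios:
        obs: list[float] = []
        for seed in seeds:
            records, _ = run_replication(scen, config, horizon_days, seed)
            obs.extend(_aggregate(records, aggregation, config.schedule.shift_of))
        out[scen.code] = GroupObservations(scen.code, obs, aggregation)
    return out


def summarize(group: GroupObservations) -> GroupSummary:
    """(n, mean, SD) summary of one scenario's observations (SD uses n-1)."""
    x = np.asarray(group.observations, dtype=float)
    if x.size < 2:
        raise ValueError(f"{group.scenario_code}: need at least 2 observations")
    return GroupSummary(
        group.scenario_code, int(x.size), float(x.mean()), float(x.std(ddof=1))
    )


def summary_table(groups: Mapping[str, GroupObservations]) -> pd.DataFrame:
    """Waiting-time summary table: code, N, mean, SD (hours)."""
    rows = []
    for code in groups:
        s = summarize(groups[code])
        rows.append({"code": code, "n": s.n, "mean": s.mean, "sd": s.sd})
    return pd.DataFrame(rows)
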