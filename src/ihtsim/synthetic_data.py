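"""Synthetic observation logs in the hand-collected transfer-log schema.

A real observation campaign records every transfer on a clipboard/Google-form
row: period code (N/M/A), clock times for request, departure, arrival(s) and
return-to-base, origin/wait/destination departments, vehicle, staff ID,
patient condition, and emergency status.  This module produces logs with
exactly that schema by running the baseline simulation on a ground-truth
configuration, so ingestion, input analysis, and the validation pipeline can
be exercised end-to-end without any real data.

Clock times are rendered HH:MM as in the field logs; lossless
minutes-from-midnight columns (``*_min``) and a ``Day`` column ride along so
round-trips do not lose precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arena_expr import DistributionSpec, parse_expression, sample
from .des_engine import CRITICAL, MINUTES_PER_DAY, run_replication
from .model_config import ModelConfig, ScenarioConfig, default_config

__all__ = [
    "ObservationRecord",
    "generate_log",
    "log_frame",
    "write_log",
    "read_log",
    "period_daily_counts",
    "ground_truth_durations",
]

#: Column order of the observation-log CSV (field-log schema + lossless extras).
LOG_COLUMNS = [
    "ID", "Time Period", "Time Request", "Departure Time", "Arrival Time",
    "Time wait for pick up", "Time Arrival (2)", "Time Finish",
    "Dept Start", "Dept Wait", "Dept End", "Vehicle", "Staff",
    "Condition", "Emergency",
    "Day", "request_min", "departure_min", "arrival_min", "wait_min",
    "arrival2_min", "finish_min",
]


@dataclass(frozen=True)
class ObservationRecord:
    id: int
    period: str  # N / M / A
    day: int
    request_min: float  # minutes from replication start
    departure_min: float
    arrival_min: float
    wait_min: Optional[float]  # waiting-for-pickup start (two-leg jobs)
    arrival2_min: Optional[float]
    finish_min: float
    dept_start: str
    dept_wait: Optional[str]
    dept_end: str
    vehicle: str  # Wheelchair / Bed
    staff_id: str
    condition: str  # "Critical ill" / "Non critical ill"
    emergency: str  # "Emergency" / "Non-emergency"


def _hhmm(minutes_from_start: float) -> str:
    m = int(round(minutes_from_start)) % int(MINUTES_PER_DAY)
    return f"{m // 60}:{m % 60:02d}"


def generate_log(
    config: Optional[ModelConfig] = None,
    days: int = 13,
    seed: int = 0,
    *,
    emergency_prob: float = 0.1,
) -> list[ObservationRecord]:
    """Generate an observation log by running the baseline (M0:1:8) model.

    Same ``(config, days, seed)`` → identical log.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    config = config if config is not None else default_config()
    baseline = ScenarioConfig(1.0, 8, frozenset())
    records, _ = run_replication(
        baseline, config, days, seed, emergency_prob=emergency_prob
    )
    name = {s.id: s.name for s in config.network.stations}
    out: list[ObservationRecord] = []
    for r in records:
        two_leg = r.intermediate is not None
        out.append(
            ObservationRecord(
                id=r.request_id,
                period=config.schedule.shift_of(r.request_time % MINUTES_PER_DAY),
                day=int(r.request_time // MINUTES_PER_DAY),
                request_min=r.request_time,
                departure_min=r.departure_time,
                arrival_min=r.arrival_time,
                wait_min=r.arrival_time if two_leg else None,
                arrival2_min=r.second_arrival_time,
                finish_min=r.finish_time,
                dept_start=name[r.origin],
                dept_wait=name[r.intermediate] if two_leg else None,
                dept_end=name[r.destination],
                vehicle="Bed" if r.vehicle == "bed" else "Wheelchair",
                staff_id=r.staff_id,
                condition="Critical ill" if r.severity == CRITICAL else "Non critical ill",
                emergency="Emergency" if r.emergency else "Non-emergency",
            )
        )
    return out


def log_frame(records: Sequence[ObservationRecord]) -> pd.DataFrame:
    """Render observation records as a DataFrame in the log schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "ID": r.id,
                "Time Period": r.period,
                "Time Request": _hhmm(r.request_min),
                "Departure Time": _hhmm(r.departure_min),
                "Arrival Time": _hhmm(r.arrival_min),
                "Time wait for pick up": _hhmm(r.wait_min) if r.wait_min is not None else "-",
                "Time Arrival (2)": _hhmm(r.arrival2_min) if r.arrival2_min is not None else "-",
                "Time Finish": _hhmm(r.finish_min),
                "Dept Start": r.dept_start,
                "Dept Wait": r.dept_wait if r.dept_wait is not None else "-",
                "Dept End": r.dept_end,
                "Vehicle": r.vehicle,
                "Staff": r.staff_id,
                "Condition": r.condition,
                "Emergency": r.emergency,
                "Day": r.day,
                "request_min": r.request_min,
                "departure_min": r.departure_min,
                "arrival_min": r.arrival_min,
                "wait_min": r.wait_min if r.wait_min is not None else np.nan,
                "arrival2_min": r.arrival2_min if r.arrival2_min is not None else np.nan,
                "finish_min": r.finish_min,
            }
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(records: Sequence[ObservationRecord], path: str | Path) -> None:
    log_frame(records).to_csv(path, index=False)


def read_log(path: str | Path) -> pd.DataFrame:
    """Read an observation-log CSV back into a DataFrame."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"log file is missing columns: {missing}")
    return df


def period_daily_counts(log: pd.DataFrame) -> pd.DataFrame:
    """Requests per (day, period) from a log frame; zero-filled.

    Output columns: Day, plus one column per period code present in the
    shift plan (N/M/A).
    """
    counts = (
        log.groupby(["Day", "Time Period"]).size().unstack(fill_value=0)
    )
    for period in "NMA":
        if period not in counts.columns:
            counts[period] = 0
    return counts[list("NMA")].reset_index()


def ground_truth_durations(
    spec: DistributionSpec | str, n: int, seed: int
) -> tuple[np.ndarray, DistributionSpec]:
    """``n`` draws plus the generating spec — parameter-recovery fixtures."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(spec, str):
        spec = parse_expression(spec)
    rng = np.random.default_rng(seed)
    return sample(spec, rng, n), spec
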