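"""Model configuration: station network, arrivals, routing, scenario grid.

The default configuration models a 26-station medical-center network.  Seven
stations (drop points, exits, transfer bases) are pass-through locations that
never originate a timed transfer; the remaining 19 each carry three fitted
distribution expressions — severity, operated time, and vehicle — exactly as
printed in the source input-analysis table.  Staff are homed at the two
transfer bases.

Per-station arrival rates and the full origin→destination routing matrix for
the study hospital were never published; the packaged defaults are calibrated
stand-ins chosen so that the expected number of requests per day and period
matches the historical means (Night 2.31, Morning 49.54, Afternoon 11.77
requests/day) while concentrating demand on the emergency and outpatient
departments, the dominant flows described for the study site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .arena_expr import DistributionSpec, parse_expression, render

__all__ = [
    "Station",
    "NetworkConfig",
    "ArrivalSchedule",
    "RoutingRule",
    "StationSpecs",
    "ModelConfig",
    "ScenarioConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "build_scenario_grid",
    "scenario_from_code",
    "scale_demand",
    "SHIFTS",
    "PERIOD_TARGETS",
]


class ConfigError(ValueError):
    """Raised when a model configuration violates its invariants."""


#: Shift windows partitioning the 24 h day (hours from midnight).
SHIFTS: tuple[tuple[str, int, int], ...] = (("N", 0, 8), ("M", 8, 16), ("A", 16, 24))

#: Calibration targets: expected requests per day in each period.
PERIOD_TARGETS: dict[str, float] = {"N": 2.31, "M": 49.54, "A": 11.77}


@dataclass(frozen=True)
class Station:
    id: int
    name: str
    is_base: bool = False


@dataclass
class NetworkConfig:
    """Stations plus the inter-station travel-time matrix (minutes)."""

    stations: list[Station]
    travel_minutes: np.ndarray

    def __post_init__(self) -> None:
        ids = [s.id for s in self.stations]
        if len(set(ids)) != len(ids):
            raise ConfigError("station ids must be unique")
        if not any(s.is_base for s in self.stations):
            raise ConfigError("at least one base station is required")
        t = np.asarray(self.travel_minutes, dtype=float)
        k = len(self.stations)
        if t.shape != (k, k):
            raise ConfigError(
                f"travel matrix shape {t.shape} does not match {k} stations"
            )
        if not np.all(np.isfinite(t)) or (t < 0).any():
            raise ConfigError("travel times must be finite and nonnegative")
        if np.diag(t).any():
            raise ConfigError("travel matrix diagonal must be zero")
        self.travel_minutes = t
        self._index = {s.id: i for i, s in enumerate(self.stations)}

    def travel(self, a: int, b: int) -> float:
        """Travel time in minutes between station ids ``a`` and ``b``."""
        return float(self.travel_minutes[self._index[a], self._index[b]])

    def station(self, sid: int) -> Station:
        return self.stations[self._index[sid]]

    @property
    def base_ids(self) -> list[int]:
        return [s.id for s in self.stations if s.is_base]


@dataclass
class ArrivalSchedule:
    """Per (station, shift) request rates in requests/hour."""

    rates: dict[tuple[int, str], float]
    shifts: tuple[tuple[str, int, int], ...] = SHIFTS

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ConfigError("arrival rates must be nonnegative")
        hours = sorted((lo, hi) for _, lo, hi in self.shifts)
        if hours[0][0] != 0 or hours[-1][1] != 24 or any(
            a[1] != b[0] for a, b in zip(hours, hours[1:])
        ):
            raise ConfigError("shifts must partition the 24 h day")

    def shift_of(self, minutes_of_day: float) -> str:
        h = (minutes_of_day / 60.0) % 24.0
        for name, lo, hi in self.shifts:
            if lo <= h < hi:
                return name
        return self.shifts[-1][0]  # h == 24 boundary

    def expected_daily_by_period(self) -> dict[str, float]:
        """Expected requests/day in each period implied by the rates."""
        out = {name: 0.0 for name, _, _ in self.shifts}
        for (sid, shift), rate in self.rates.items():
            hours = next(hi - lo for name, lo, hi in self.shifts if name == shift)
            out[shift] += rate * hours
        return out


@dataclass
class RoutingRule:
    """Destination mixing and wait-and-return (two-leg) channel per origin."""

    dest_probs: dict[int, dict[int, float]]
    two_leg_prob: dict[int, float] = field(default_factory=dict)
    intermediate_probs: dict[int, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for origin, probs in self.dest_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"destination probabilities for station {origin} sum to {total}"
                )
            if probs.get(origin, 0.0) == 1.0:
                raise ConfigError(f"station {origin} routes only to itself")
        for origin, p in self.two_leg_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"two-leg probability for {origin} outside [0,1]")
            if p > 0:
                inter = self.intermediate_probs.get(origin, {})
                total = sum(inter.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"intermediate probabilities for station {origin} sum to {total}"
                    )


@dataclass
class StationSpecs:
    """The three fitted distribution expressions attached to one station."""

    severity: DistributionSpec
    operated_time: DistributionSpec
    vehicle: DistributionSpec


@dataclass
class ModelConfig:
    network: NetworkConfig
    schedule: ArrivalSchedule
    routing: RoutingRule
    specs: dict[int, StationSpecs]

    def __post_init__(self) -> None:
        ids = {s.id for s in self.network.stations}
        for sid in self.specs:
            if sid not in ids:
                raise ConfigError(f"spec refers to unknown station {sid}")
        for (sid, _), rate in self.schedule.rates.items():
            if rate > 0 and sid not in self.specs:
                raise ConfigError(
                    f"station {sid} has arrivals but no severity/duration specs"
                )


# ---------------------------------------------------------------------------
# Packaged default configuration
# ---------------------------------------------------------------------------

# id, name, is_base (staff home), (x metres, floor) for the travel model.
_DEFAULT_STATIONS = [
    (1, "Drop point ER", False, (0, 1)),
    (2, "ER", False, (20, 1)),
    (3, "OPD", False, (120, 1)),
    (4, "Drop point OPD", False, (140, 1)),
    (5, "X-ray", False, (60, 1)),
    (6, "Ground Floor", False, (80, 1)),
    (7, "Screen point/Register", False, (110, 1)),
    (8, "Cashier/Pharmacy", False, (100, 1)),
    (9, "OPD-Room", False, (130, 2)),
    (10, "Physiotherapy", False, (150, 2)),
    (11, "Lab Floor1", False, (70, 1)),
    (12, "Exit", False, (90, 1)),
    (13, "Cardiac Center", False, (60, 3)),
    (14, "OPD EENT", False, (120, 3)),
    (15, "ICU", False, (40, 2)),
    (16, "Refer out", False, (10, 1)),
    (17, "Cath Lab", False, (50, 3)),
    (18, "Lab Floor3", False, (70, 3)),
    (19, "Labor room", False, (90, 4)),
    (20, "OPD Transfer Base", True, (125, 1)),
    (21, "CCU", False, (45, 2)),
    (22, "OB Gyne", False, (100, 4)),
    (23, "OR", False, (30, 3)),
    (24, "IPD9", False, (60, 5)),
    (25, "ER Transfer Base", True, (15, 1)),
    (26, "IPD10", False, (60, 6)),
]

# Fitted input-analysis expressions per station (severity, operated time,
# vehicle).  Stations absent here are pass-through locations.
_DEFAULT_SPECS: dict[int, tuple[str, str, str]] = {
    2: ("DISC(0.804123711340206,1,1,2)", "2.5 + 16 * BETA(0.571, 1.73)", "DISC(0.814432989690722,1,1,2)"),
    3: ("DISC(1,1,1,2)", "0.5 + LOGN(5.1, 3.45)", "DISC(0.96969696969697,1,1,2)"),
    5: ("DISC(0.758333333333333,1,1,2)", "1.5 + GAMM(5.78, 2.4)", "DISC(0.666666666666667,1,1,2)"),
    7: ("DISC(1,1,1,2)", "1.5 + GAMM(2.4, 2.5)", "DISC(1,1,1,2)"),
    8: ("DISC(1,1,1,2)", "1.5 + ERLA(2.97, 2)", "DISC(0.981132075471698,1,1,2)"),
    9: ("DISC(1,1,1,2)", "0.5 + LOGN(7.62, 7.53)", "DISC(0.8,1,1,2)"),
    10: ("DISC(1,1,1,2)", "0.5 + LOGN(6.34, 6.3)", "DISC(0.964285714285714,1,1,2)"),
    11: ("DISC(1,1,1,2)", "NORM(11.5, 4.11)", "DISC(1,1,1,2)"),
    13: ("DISC(0.904761904761905,1,1,2)", "1.5 + 17 * BETA(1.78, 1.42)", "DISC(0.857142857142857,1,1,2)"),
    14: ("DISC(1,1,1,2)", "3.5 + WEIB(7.77, 1.85)", "DISC(1,1,1,2)"),
    15: ("DISC(0,1,1,2)", "UNIF(7.5, 18.5)", "DISC(0,1,1,2)"),
    17: ("DISC(1,1,1,2)", "5.5 + 13 * BETA(1.45, 1.25)", "DISC(0.125,1,1,2)"),
    18: ("DISC(1,1,1,2)", "TRIA(3.5, 9, 18.5)", "DISC(0.888888888888889,1,1,2)"),
    19: ("DISC(0.96875,1,1,2)", "POIS(15.5)", "DISC(0.0625,1,1,2)"),
    21: ("DISC(0.25,1,1,2)", "POIS(10.7)", "DISC(0.25,1,1,2)"),
    22: ("DISC(1,1,1,2)", "4.5 + ERLA(5.08, 2)", "DISC(0.588235294117647,1,1,2)"),
    23: ("DISC(1,1,1,2)", "1.5 + WEIB(13.8, 2.74)", "DISC(0.470588235294118,1,1,2)"),
    24: ("DISC(1,1,1,2)", "5.5 + 5 * BETA(1.34, 1.34)", "DISC(1,1,1,2)"),
    26: ("DISC(1,1,1,2)", "1.5 + 4 * BETA(1.21, 1.29)", "DISC(1,1,1,2)"),
}

# Share of each period's demand originating at each spec-bearing station.
_DEFAULT_WEIGHTS: dict[int, float] = {
    2: 0.30, 3: 0.10, 5: 0.07, 7: 0.06, 8: 0.06, 9: 0.05, 10: 0.03,
    11: 0.05, 13: 0.04, 14: 0.03, 15: 0.03, 17: 0.02, 18: 0.03, 19: 0.02,
    21: 0.03, 22: 0.02, 23: 0.03, 24: 0.02, 26: 0.01,
}

# Destination mixes for the dominant flows (ED→radiology/wards, ward→ICU/OR,
# ICU→ward, everything else toward discharge); two-leg = wait-and-return.
_DEFAULT_ROUTING: dict[int, dict[int, float]] = {
    2: {24: 0.28, 26: 0.14, 12: 0.22, 8: 0.10, 15: 0.10, 23: 0.08, 1: 0.08},
    3: {5: 0.30, 11: 0.20, 12: 0.25, 9: 0.15, 24: 0.10},
    5: {2: 0.40, 3: 0.30, 12: 0.30},
    7: {3: 0.50, 9: 0.30, 12: 0.20},
    8: {12: 0.70, 4: 0.30},
    9: {8: 0.40, 12: 0.30, 5: 0.20, 24: 0.10},
    10: {12: 0.60, 24: 0.25, 26: 0.15},
    11: {3: 0.50, 12: 0.30, 9: 0.20},
    13: {17: 0.35, 21: 0.30, 12: 0.20, 24: 0.15},
    14: {12: 0.55, 8: 0.30, 24: 0.15},
    15: {24: 0.45, 26: 0.30, 23: 0.25},
    17: {21: 0.45, 15: 0.30, 24: 0.25},
    18: {14: 0.40, 12: 0.35, 24: 0.25},
    19: {22: 0.60, 23: 0.25, 24: 0.15},
    21: {24: 0.40, 26: 0.25, 12: 0.20, 15: 0.15},
    22: {19: 0.35, 12: 0.35, 24: 0.30},
    23: {15: 0.40, 21: 0.20, 24: 0.25, 26: 0.15},
    24: {12: 0.50, 5: 0.25, 23: 0.25},
    26: {12: 0.55, 5: 0.25, 23: 0.20},
}

# Wait-and-return: mostly ED round trips through imaging.
_DEFAULT_TWO_LEG: dict[int, float] = {2: 0.10, 3: 0.05, 24: 0.05, 26: 0.05}
_DEFAULT_INTERMEDIATE: dict[int, dict[int, float]] = {
    2: {5: 1.0},
    3: {5: 0.7, 11: 0.3},
    24: {5: 1.0},
    26: {5: 1.0},
}


def _default_travel_matrix() -> np.ndarray:
    """Walking/elevator times from synthetic blueprint coordinates.

    Horizontal distance contributes at ~80 m/min; each floor change adds a
    fixed elevator penalty.  Entries land in roughly 0.5–5 minutes, the
    plausible scale for a single-building medical center.
    """
    coords = {sid: xy for sid, _, _, xy in _DEFAULT_STATIONS}
    ids = [sid for sid, *_ in _DEFAULT_STATIONS]
    k = len(ids)
    t = np.zeros((k, k))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            (xa, fa), (xb, fb) = coords[a], coords[b]
            t[i, j] = round(0.4 + abs(xa - xb) / 80.0 + 0.9 * abs(fa - fb), 2)
    return t


def default_config() -> ModelConfig:
    """The packaged default 26-station configuration."""
    stations = [Station(sid, name, base) for sid, name, base, _ in _DEFAULT_STATIONS]
    network = NetworkConfig(stations, _default_travel_matrix())
    rates: dict[tuple[int, str], float] = {}
    for shift, lo, hi in SHIFTS:
        total = PERIOD_TARGETS[shift]
        hours = hi - lo
        for sid, w in _DEFAULT_WEIGHTS.items():
            rates[(sid, shift)] = w * total / hours
    schedule = ArrivalSchedule(rates)
    routing = RoutingRule(
        {o: dict(d) for o, d in _DEFAULT_ROUTING.items()},
        dict(_DEFAULT_TWO_LEG),
        {o: dict(d) for o, d in _DEFAULT_INTERMEDIATE.items()},
    )
    specs = {
        sid: StationSpecs(*(parse_expression(e) for e in exprs))
        for sid, exprs in _DEFAULT_SPECS.items()
    }
    return ModelConfig(network, schedule, routing, specs)


# ---------------------------------------------------------------------------
# Config file I/O (YAML with distribution expressions as strings)
# ---------------------------------------------------------------------------


def save_config(config: ModelConfig, path: str | Path) -> None:
    doc = {
        "stations": [
            {"id": s.id, "name": s.name, "is_base": s.is_base}
            for s in config.network.stations
        ],
        "travel_minutes": config.network.travel_minutes.tolist(),
        "shifts": [
            {"name": n, "start": lo, "end": hi} for n, lo, hi in config.schedule.shifts
        ],
        "arrival_rates": {
            f"{sid}:{shift}": rate
            for (sid, shift), rate in sorted(config.schedule.rates.items())
        },
        "routing": {
            str(o): {str(d): p for d, p in probs.items()}
            for o, probs in config.routing.dest_probs.items()
        },
        "two_leg_prob": {str(o): p for o, p in config.routing.two_leg_prob.items()},
        "intermediate": {
            str(o): {str(d): p for d, p in probs.items()}
            for o, probs in config.routing.intermediate_probs.items()
        },
        "specs": {
            str(sid): {
                "severity": render(sp.severity),
                "operated_time": render(sp.operated_time),
                "vehicle": render(sp.vehicle),
            }
            for sid, sp in config.specs.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a configuration file written by :func:`save_config`."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        stations = [
            Station(int(s["id"]), str(s["name"]), bool(s.get("is_base", False)))
            for s in doc["stations"]
        ]
        network = NetworkConfig(stations, np.asarray(doc["travel_minutes"], float))
        shifts = tuple(
            (str(s["name"]), int(s["start"]), int(s["end"])) for s in doc["shifts"]
        )
        rates = {}
        for key, rate in doc.get("arrival_rates", {}).items():
            sid, shift = str(key).split(":")
            rates[(int(sid), shift)] = float(rate)
        schedule = ArrivalSchedule(rates, shifts)
        routing = RoutingRule(
            {
                int(o): {int(d): float(p) for d, p in probs.items()}
                for o, probs in doc.get("routing", {}).items()
            },
            {int(o): float(p) for o, p in doc.get("two_leg_prob", {}).items()},
            {
                int(o): {int(d): float(p) for d, p in probs.items()}
                for o, probs in doc.get("intermediate", {}).items()
            },
        )
        specs = {
            int(sid): StationSpecs(
                parse_expression(sp["severity"]),
                parse_expression(sp["operated_time"]),
                parse_expression(sp["vehicle"]),
            )
            for sid, sp in doc.get("specs", {}).items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed configuration file: missing {exc}") from exc
    return ModelConfig(network, schedule, routing, specs)


# ---------------------------------------------------------------------------
# Scenario grid
# ---------------------------------------------------------------------------

_POLICY_SETS: tuple[frozenset[str], ...] = (
    frozenset(),
    frozenset("a"),
    frozenset("ab"),
    frozenset("abc"),
    frozenset("abd"),
)

_POLICY_ORDER = "abcd"


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the experiment grid.

    ``code`` follows the ``M<policies>:<demand level>:<staff>`` convention:
    policies ``0`` (none) or a subset of ``abcd``; demand level 1 = 100%,
    2 = 120%; staff count 8 (normal) or 6 (reduced).
    """

    demand_multiplier: float
    staff_count: int
    policy_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.policy_set not in _POLICY_SETS:
            raise ConfigError(f"unsupported policy set {set(self.policy_set)}")
        if self.demand_multiplier not in (1.0, 1.2):
            raise ConfigError(f"demand multiplier must be 1.0 or 1.2")
        if self.staff_count not in (6, 8):
            raise ConfigError("staff count must be 6 or 8")

    @property
    def code(self) -> str:
        letters = "".join(c for c in _POLICY_ORDER if c in self.policy_set) or "0"
        level = 1 if self.demand_multiplier == 1.0 else 2
        return f"M{letters}:{level}:{self.staff_count}"


def scenario_from_code(code: str) -> ScenarioConfig:
    """Parse a scenario code like ``"Mabc:2:6"`` back to its configuration."""
    try:
        head, level, staff = code.split(":")
        if not head.startswith("M"):
            raise ValueError
        letters = head[1:]
        policies = frozenset() if letters == "0" else frozenset(letters)
        mult = {1: 1.0, 2: 1.2}[int(level)]
        return ScenarioConfig(mult, int(staff), policies)
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"malformed scenario code {code!r}") from exc


def build_scenario_grid() -> list[ScenarioConfig]:
    """The full 20-scenario grid: 5 policy sets x 2 demand levels x 2 rosters."""
    return [
        ScenarioConfig(mult, staff, pol)
        for pol in _POLICY_SETS
        for mult in (1.0, 1.2)
        for staff in (8, 6)
    ]


def scale_demand(schedule: ArrivalSchedule, multiplier: float) -> ArrivalSchedule:
    """Return a schedule with every rate multiplied; shift windows unchanged."""
    if multiplier <= 0:
        raise ConfigError("demand multiplier must be positive")
    return ArrivalSchedule(
        {key: rate * multiplier for key, rate in schedule.rates.items()},
        schedule.shifts,
    )
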