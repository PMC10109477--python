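"""Event-driven simulation of transfer requests and staff dispatch.

The engine models a transfer center receiving patient-move requests at the
network's stations.  Each request needs one porter (staff agent) who travels
from wherever they are to the patient's origin, moves the patient to the
destination (the origin station's fitted operated-time draw covers that loaded
move), optionally waits out a procedure and brings the patient back
(wait-and-return jobs), and finally returns to their home base.  The travel
matrix times only the *empty* repositioning moves; the loaded move is the
operated time.

Four dispatch policy letters modify the baseline FIFO / return-to-base flow:

``a``
    serve the most severe queued patient first (critical before non-critical,
    FIFO within a class);
``b``
    after delivering a patient, take the next queued job directly from the
    delivery location instead of returning to base (return only when the
    queue is empty);
``c``
    among idle staff, pick the one nearest (by travel time) to the patient;
``d``
    among idle staff, pick the one with the least cumulative working time.

Everything random is drawn up front from three named substreams (arrival
counts/times, request attributes, service durations) spawned from one master
seed, so replications are bit-reproducible and policy variants compare under
common random numbers.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .arena_expr import sample, sample_nonnegative
from .model_config import (
    ArrivalSchedule,
    ModelConfig,
    NetworkConfig,
    RoutingRule,
    ScenarioConfig,
    StationSpecs,
)

__all__ = [
    "TransferRequest",
    "StaffAgent",
    "TransferRecord",
    "SimState",
    "generate_arrivals",
    "queue_discipline",
    "select_staff",
    "run_replication",
    "simulate_requests",
]

MINUTES_PER_DAY = 1440.0

CRITICAL = "critical"
NON_CRITICAL = "non-critical"


@dataclass
class TransferRequest:
    id: int
    request_time: float  # minutes from replication start
    origin: int
    destination: int
    intermediate: Optional[int]
    severity: str  # CRITICAL or NON_CRITICAL
    emergency: bool
    vehicle: str  # "wheelchair" or "bed"
    # Pre-drawn service durations (minutes), so every policy variant sees the
    # identical job under common random numbers.
    service_leg1: float = 0.0
    wait_intermediate: float = 0.0
    service_leg2: float = 0.0


@dataclass
class StaffAgent:
    id: str
    home_base: int
    location: int
    state: str = "idle"  # idle | traveling | serving | returning
    busy_minutes: float = 0.0

    @property
    def index(self) -> int:
        return int(self.id.lstrip("ST"))


@dataclass
class TransferRecord:
    request_id: int
    request_time: float
    departure_time: float
    arrival_time: float
    second_arrival_time: Optional[float]
    finish_time: float
    staff_id: str
    origin: int
    destination: int
    intermediate: Optional[int]
    severity: str
    emergency: bool
    vehicle: str
    overtime: bool = False

    @property
    def waiting_minutes(self) -> float:
        return self.departure_time - self.request_time


@dataclass
class SimState:
    clock: float
    pending: list[TransferRequest]
    roster: list[StaffAgent]
    completed: list[TransferRecord]
    rng: np.random.Generator


# ---------------------------------------------------------------------------
# Arrival generation
# ---------------------------------------------------------------------------


def generate_arrivals(
    schedule: ArrivalSchedule,
    routing: RoutingRule,
    specs: Mapping[int, StationSpecs],
    demand_multiplier: float,
    horizon_days: int,
    rng: np.random.Generator,
    *,
    emergency_prob: float = 0.1,
) -> list[TransferRequest]:
    """Draw the full request stream for one replication.

    Counts per (station, shift, day) are Poisson with the scaled rate; times
    are uniform within the shift.  Severity and vehicle come from the origin
    station's fitted discrete specs; destination and the wait-and-return
    channel from the routing rule; service durations are pre-drawn here.

    Common-random-number structure: a demand multiplier above 1 is realized
    by SUPERPOSING an independent extra Poisson stream of rate
    ``(multiplier - 1) x base`` on top of the unchanged base stream, and every
    request draws its attributes and durations from its own keyed substream.
    The base-demand jobs are therefore bit-identical across multipliers (and
    across policy variants), so load and policy contrasts are paired.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    master = int(rng.integers(2**31 - 1))

    raw: list[tuple[float, int, int, int, int]] = []  # (t, sid, shift_i, day, idx)
    for sid in sorted({s for s, _ in schedule.rates}):
        for si, (shift, lo, hi) in enumerate(schedule.shifts):
            rate = schedule.rates.get((sid, shift), 0.0)
            if rate <= 0:
                continue
            hours = hi - lo
            streams = [(0, rate if demand_multiplier >= 1.0 else rate * demand_multiplier)]
            if demand_multiplier > 1.0:
                streams.append((1, rate * (demand_multiplier - 1.0)))
            for day in range(horizon_days):
                for flag, r in streams:
                    cell = np.random.default_rng([master, flag, sid, si, day])
                    n = cell.poisson(r * hours)
                    if n == 0:
                        continue
                    times = day * MINUTES_PER_DAY + 60.0 * (lo + hours * cell.random(n))
                    raw.extend(
                        (float(t), sid, si, day, 2 * i + flag)
                        for i, t in enumerate(times)
                    )
    raw.sort()

    requests: list[TransferRequest] = []
    for rid, (t, origin, si, day, idx) in enumerate(raw, start=1):
        st = specs[origin]
        req_rng = np.random.default_rng([master, 3, origin, si, day, idx])
        sev_code = int(sample(st.severity, req_rng, 1)[0])
        veh_code = int(sample(st.vehicle, req_rng, 1)[0])
        severity = CRITICAL if sev_code == 2 else NON_CRITICAL
        vehicle = "bed" if veh_code == 2 else "wheelchair"
        emergency = bool(req_rng.random() < emergency_prob)

        intermediate: Optional[int] = None
        if req_rng.random() < routing.two_leg_prob.get(origin, 0.0):
            inter = routing.intermediate_probs[origin]
            ids, probs = zip(*sorted(inter.items()))
            intermediate = int(ids[_pick(req_rng, probs)])
            destination = origin  # wait-and-return round trip
        else:
            dests = routing.dest_probs[origin]
            ids, probs = zip(*sorted(dests.items()))
            destination = int(ids[_pick(req_rng, probs)])

        leg1 = float(sample_nonnegative(st.operated_time, req_rng, 1)[0])
        wait = leg2 = 0.0
        if intermediate is not None:
            mid_spec = specs.get(intermediate, st).operated_time
            wait = float(sample_nonnegative(mid_spec, req_rng, 1)[0])
            leg2 = float(sample_nonnegative(mid_spec, req_rng, 1)[0])

        requests.append(
            TransferRequest(
                rid, t, origin, destination, intermediate, severity,
                emergency, vehicle, leg1, wait, leg2,
            )
        )
    return requests


def _pick(rng: np.random.Generator, probs: Iterable[float]) -> int:
    cum = np.cumsum(np.fromiter(probs, dtype=float))
    return int(np.searchsorted(cum / cum[-1], rng.random(), side="right"))


# ---------------------------------------------------------------------------
# Dispatch rules
# ---------------------------------------------------------------------------


def queue_discipline(
    pending: list[TransferRequest], policy_set: frozenset[str] | set[str]
) -> TransferRequest:
    """The queued request to serve next (queue is left untouched).

    Policy ``a``: critical patients first, FIFO within a severity class;
    otherwise strict FIFO.  Ties broken by request id.
    """
    if not pending:
        raise ValueError("pending queue is empty")
    if "a" in policy_set:
        key = lambda r: (0 if r.severity == CRITICAL else 1, r.request_time, r.id)
    else:
        key = lambda r: (r.request_time, r.id)
    return min(pending, key=key)


def select_staff(
    state: SimState,
    request: TransferRequest,
    policy_set: frozenset[str] | set[str],
    network: NetworkConfig,
) -> Optional[StaffAgent]:
    """The idle staff agent to dispatch, or ``None`` if nobody is idle.

    Default: lowest staff index.  Policy ``c``: minimum travel time from the
    agent's location to the request origin.  Policy ``d``: minimum cumulative
    working time.  Ties always break toward the lowest staff index.
    """
    idle = [s for s in state.roster if s.state == "idle"]
    if not idle:
        return None
    if "c" in policy_set:
        key = lambda s: (network.travel(s.location, request.origin), s.index)
    elif "d" in policy_set:
        key = lambda s: (s.busy_minutes, s.index)
    else:
        key = lambda s: s.index
    return min(idle, key=key)


# ---------------------------------------------------------------------------
# Replication loop
# ---------------------------------------------------------------------------

# Event kinds ordered for same-timestamp processing: deliveries first (so a
# chaining porter grabs the queue state as of the delivery), then staff
# returning to base, then new arrivals.
_EV_DELIVERED, _EV_STAFF_FREE, _EV_ARRIVAL = 0, 1, 2


def _build_roster(
    network: NetworkConfig, staff_count: int, schedule: ArrivalSchedule
) -> list[StaffAgent]:
    """Round-robin the roster over home bases, demand-nearest base first.

    Bases are ordered by the rate-weighted expected travel time to request
    origins, so the lowest staff indices sit at the base serving the bulk of
    the demand (the emergency-side base in the default network) — the way a
    real transfer center allocates its porters.
    """
    if staff_count < 1:
        raise ValueError("staff_count must be >= 1")
    total_rate: dict[int, float] = {}
    for (sid, _), rate in schedule.rates.items():
        total_rate[sid] = total_rate.get(sid, 0.0) + rate
    def score(base: int) -> tuple[float, int]:
        return (
            sum(r * network.travel(base, sid) for sid, r in total_rate.items()),
            base,
        )
    bases = sorted(network.base_ids, key=score)
    return [
        StaffAgent(f"ST{i:02d}", bases[(i - 1) % len(bases)], bases[(i - 1) % len(bases)])
        for i in range(1, staff_count + 1)
    ]


def run_replication(
    scenario: ScenarioConfig,
    config: ModelConfig,
    horizon_days: int,
    seed: int,
    *,
    emergency_prob: float = 0.1,
) -> tuple[list[TransferRecord], dict[str, float]]:
    """Run one replication; returns (records, per-staff utilization).

    Identical ``(scenario, config, seed)`` triples give bit-identical output.
    Requests still in flight at the horizon are completed in overtime and
    flagged rather than dropped, so completed == generated always holds.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    arr_rng = np.random.default_rng(np.random.SeedSequence(seed))

    requests = generate_arrivals(
        config.schedule,
        config.routing,
        config.specs,
        scenario.demand_multiplier,
        horizon_days,
        arr_rng,
        emergency_prob=emergency_prob,
    )
    roster = _build_roster(config.network, scenario.staff_count, config.schedule)
    return simulate_requests(
        requests, config, scenario.policy_set, roster,
        horizon_min=horizon_days * MINUTES_PER_DAY,
    )


def simulate_requests(
    requests: Sequence[TransferRequest],
    config: ModelConfig,
    policy_set: frozenset[str] | set[str],
    roster: Sequence[StaffAgent],
    *,
    horizon_min: float,
) -> tuple[list[TransferRecord], dict[str, float]]:
    """Run the dispatch event loop over an explicit request list.

    This is the deterministic core of :func:`run_replication`, exposed so
    hand-constructed schedules can be traced exactly.
    """
    network = config.network
    policies = frozenset(policy_set)
    roster = list(roster)
    state = SimState(0.0, [], roster, [], np.random.default_rng(0))

    events: list[tuple[float, int, int, object]] = []
    seq = 0

    def push(time: float, kind: int, payload: object) -> None:
        nonlocal seq
        heapq.heappush(events, (time, kind, seq, payload))
        seq += 1

    for req in requests:
        push(req.request_time, _EV_ARRIVAL, req)

    def start_job(staff: StaffAgent, req: TransferRequest, now: float) -> None:
        """Commit a staff agent to a request; schedules the delivery event."""
        staff.state = "serving"
        departure = now + network.travel(staff.location, req.origin)
        arrival1 = departure + req.service_leg1
        second_arrival = None
        delivery = arrival1
        if req.intermediate is not None:
            second_arrival = arrival1 + req.wait_intermediate + req.service_leg2
            delivery = second_arrival
        staff.busy_minutes += delivery - now
        rec = TransferRecord(
            req.id, req.request_time, departure, arrival1, second_arrival,
            delivery,  # finish updated at delivery/return
            staff.id, req.origin, req.destination, req.intermediate,
            req.severity, req.emergency, req.vehicle,
        )
        push(delivery, _EV_DELIVERED, (staff, rec))

    def dispatch(now: float) -> None:
        while state.pending:
            req = queue_discipline(state.pending, policies)
            staff = select_staff(state, req, policies, network)
            if staff is None:
                return
            state.pending.remove(req)
            start_job(staff, req, now)

    while events:
        now, kind, _, payload = heapq.heappop(events)
        state.clock = now
        if kind == _EV_ARRIVAL:
            state.pending.append(payload)
            dispatch(now)
        elif kind == _EV_DELIVERED:
            staff, rec = payload
            staff.location = rec.destination
            if "b" in policies and state.pending:
                rec.finish_time = now  # handoff: next job taken immediately
                _finalize(state, rec, horizon_min)
                nxt = queue_discipline(state.pending, policies)
                state.pending.remove(nxt)
                start_job(staff, nxt, now)
            else:
                back = network.travel(staff.location, staff.home_base)
                rec.finish_time = now + back
                staff.busy_minutes += back
                staff.state = "returning"
                _finalize(state, rec, horizon_min)
                push(now + back, _EV_STAFF_FREE, staff)
        else:  # _EV_STAFF_FREE
            staff = payload
            staff.location = staff.home_base
            staff.state = "idle"
            if state.pending:
                dispatch(now)

    assert not state.pending, "conservation violated: requests left pending"
    records = sorted(state.completed, key=lambda r: r.request_id)
    span = max(horizon_min, max((r.finish_time for r in records), default=horizon_min))
    utilization = {s.id: s.busy_minutes / span for s in roster}
    return records, utilization


def _finalize(state: SimState, rec: TransferRecord, horizon_min: float) -> None:
    rec.overtime = rec.finish_time > horizon_min
    state.completed.append(rec)
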