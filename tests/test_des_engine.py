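"""Dispatch engine: queue discipline, staff selection, traced schedules."""

from __future__ import annotations

import numpy as np
import pytest

from ihtsim import (
    ScenarioConfig,
    StaffAgent,
    TransferRequest,
    generate_arrivals,
    queue_discipline,
    run_replication,
    select_staff,
    simulate_requests,
)
from ihtsim.des_engine import CRITICAL, NON_CRITICAL, SimState
from tests.conftest import make_tiny_config


def req(rid, t, *, origin=2, dest=3, sev=NON_CRITICAL, inter=None,
        leg1=10.0, wait=0.0, leg2=0.0):
    return TransferRequest(rid, t, origin, dest, inter, sev, False,
                           "wheelchair", leg1, wait, leg2)


def staff(i, base=1, loc=None, busy=0.0, state="idle"):
    return StaffAgent(f"ST{i:02d}", base, loc if loc is not None else base,
                      state, busy)


class TestQueueDiscipline:
    def test_fifo_ignores_severity(self):
        pending = [req(1, 1.0, sev=CRITICAL), req(2, 0.0)]
        assert queue_discipline(pending, frozenset()).id == 2

    def test_policy_a_serves_critical_first(self):
        pending = [req(1, 1.0, sev=CRITICAL), req(2, 0.0)]
        assert queue_discipline(pending, frozenset("a")).id == 1

    def test_policy_a_fifo_within_severity_class(self):
        pending = [req(1, 5.0, sev=CRITICAL), req(2, 3.0, sev=CRITICAL)]
        assert queue_discipline(pending, frozenset("a")).id == 2

    def test_tie_broken_by_request_id(self):
        pending = [req(2, 1.0), req(1, 1.0)]
        assert queue_discipline(pending, frozenset()).id == 1


class TestSelectStaff:
    def _state(self, roster):
        return SimState(0.0, [], roster, [], np.random.default_rng(0))

    def test_single_idle_staff_selected(self, tiny_config):
        st = self._state([staff(1)])
        assert select_staff(st, req(1, 0.0), frozenset(), tiny_config.network).id == "ST01"

    def test_default_lowest_index(self, tiny_config):
        st = self._state([staff(2), staff(1)])
        assert select_staff(st, req(1, 0.0), frozenset(), tiny_config.network).id == "ST01"

    def test_policy_c_nearest_staff(self, tiny_config):
        # ST01 idle at base (2 min from origin), ST02 idle at destination
        # (1.5 min from origin): policy c must pick ST02.
        st = self._state([staff(1, loc=1), staff(2, loc=3)])
        assert select_staff(st, req(1, 0.0), frozenset("abc"), tiny_config.network).id == "ST02"

    def test_policy_d_least_worked_staff(self, tiny_config):
        st = self._state([staff(1, busy=120.0), staff(2, busy=45.0)])
        assert select_staff(st, req(1, 0.0), frozenset("abd"), tiny_config.network).id == "ST02"

    def test_no_idle_staff_returns_none(self, tiny_config):
        st = self._state([staff(1, state="serving")])
        assert select_staff(st, req(1, 0.0), frozenset(), tiny_config.network) is None


class TestTracedSchedules:
    def test_empty_system_co_located_staff(self):
        """One request, staff already at the origin, service 10 min:
        waiting 0 and finish = request + service + return travel."""
        cfg = make_tiny_config(d_base_origin=0.0)
        recs, _ = simulate_requests(
            [req(1, 5.0)], cfg, frozenset(), [staff(1)], horizon_min=1440
        )
        (r,) = recs
        assert r.waiting_minutes == 0.0
        assert r.arrival_time == 5.0 + 10.0
        assert r.finish_time == 5.0 + 10.0 + cfg.network.travel(3, 1)

    def test_travel_to_origin_delays_departure(self, tiny_config):
        recs, _ = simulate_requests(
            [req(1, 0.0)], tiny_config, frozenset(), [staff(1)], horizon_min=1440
        )
        assert recs[0].departure_time == pytest.approx(2.0)  # base→origin travel
        assert recs[0].waiting_minutes == pytest.approx(2.0)

    def test_policy_b_chains_without_returning_to_base(self, tiny_config):
        """Two back-to-back jobs, one porter.  Without b the second departure
        waits out the return trip (dest→base→origin); with b the porter cuts
        straight across (dest→origin).  Departure gap = 3 + 2 − 1.5 = 3.5."""
        jobs = lambda: [req(1, 0.0), req(2, 0.5)]
        no_b, _ = simulate_requests(
            jobs(), tiny_config, frozenset(), [staff(1)], horizon_min=1440
        )
        with_b, _ = simulate_requests(
            jobs(), tiny_config, frozenset("b"), [staff(1)], horizon_min=1440
        )
        # job 1: depart 2, deliver 12; no-b: home at 15, depart job 2 at 17.
        assert no_b[1].departure_time == pytest.approx(17.0)
        # with b: leave dest at 12, reach origin at 13.5.
        assert with_b[1].departure_time == pytest.approx(13.5)
        gap = no_b[1].departure_time - with_b[1].departure_time
        d = tiny_config.network.travel
        assert gap == pytest.approx(d(3, 1) + d(1, 2) - d(3, 2))
        # chained job 1 ends at handoff; final job still returns to base.
        assert with_b[0].finish_time == pytest.approx(12.0)
        assert with_b[1].finish_time == pytest.approx(13.5 + 10.0 + d(3, 1))

    def test_wait_and_return_record_has_two_legs(self):
        cfg = make_tiny_config(two_leg=True)
        r = req(1, 0.0, dest=2, inter=4, leg1=7.0, wait=3.0, leg2=4.0)
        recs, _ = simulate_requests([r], cfg, frozenset(), [staff(1)], horizon_min=1440)
        rec = recs[0]
        assert rec.second_arrival_time is not None
        assert rec.departure_time == pytest.approx(2.0)
        assert rec.arrival_time == pytest.approx(9.0)  # at imaging
        assert rec.second_arrival_time == pytest.approx(9.0 + 3.0 + 4.0)
        assert rec.finish_time == pytest.approx(16.0 + cfg.network.travel(2, 1))

    def test_priority_order_under_policy_a(self, tiny_config):
        """Requests queued behind a busy porter leave in severity-then-time
        order: criticals drain before any older non-critical."""
        jobs = [
            req(1, 0.0),                      # dispatched immediately
            req(2, 1.0),                      # non-critical
            req(3, 2.0, sev=CRITICAL),
            req(4, 3.0),                      # non-critical
            req(5, 4.0, sev=CRITICAL),
        ]
        recs, _ = simulate_requests(
            jobs, tiny_config, frozenset("a"), [staff(1)], horizon_min=1440
        )
        order = [r.request_id for r in sorted(recs, key=lambda r: r.departure_time)]
        assert order == [1, 3, 5, 2, 4]

    def test_timestamps_monotone_within_record(self, config):
        recs, _ = run_replication(ScenarioConfig(1.0, 8, frozenset()), config, 2, 11)
        for r in recs:
            ts = [r.request_time, r.departure_time, r.arrival_time]
            if r.second_arrival_time is not None:
                ts.append(r.second_arrival_time)
            ts.append(r.finish_time)
            assert all(a <= b + 1e-9 for a, b in zip(ts, ts[1:]))
            assert r.waiting_minutes >= 0


class TestReplication:
    def test_same_seed_bit_identical(self, config):
        scen = ScenarioConfig(1.2, 6, frozenset("abc"))
        a, ua = run_replication(scen, config, 3, 77)
        b, ub = run_replication(scen, config, 3, 77)
        assert a == b and ua == ub

    def test_conservation_every_request_recorded(self, config):
        scen = ScenarioConfig(1.0, 8, frozenset())
        recs, _ = run_replication(scen, config, 3, 19)
        reqs = generate_arrivals(
            config.schedule, config.routing, config.specs, 1.0, 3,
            np.random.default_rng(np.random.SeedSequence(19)),
        )
        assert len(recs) == len(reqs)
        assert [r.request_id for r in recs] == [q.id for q in reqs]

    def test_utilization_positive_and_bounded(self, config):
        _, util = run_replication(ScenarioConfig(1.0, 8, frozenset()), config, 2, 3)
        assert all(0 <= u <= 1 for u in util.values())
        assert any(u > 0 for u in util.values())

    def test_zero_rates_give_empty_run(self, tiny_config):
        recs, util = run_replication(
            ScenarioConfig(1.0, 8, frozenset()), tiny_config, 1, 0
        )
        assert recs == [] and all(u == 0 for u in util.values())

    def test_base_demand_jobs_identical_across_multipliers(self, config):
        """The 100% request stream is a subset of the 120% stream (paired
        demand contrast by superposition)."""
        lo = generate_arrivals(
            config.schedule, config.routing, config.specs, 1.0, 2,
            np.random.default_rng(np.random.SeedSequence(5)),
        )
        hi = generate_arrivals(
            config.schedule, config.routing, config.specs, 1.2, 2,
            np.random.default_rng(np.random.SeedSequence(5)),
        )
        key = lambda r: (r.request_time, r.origin, r.destination, r.severity,
                         r.vehicle, r.service_leg1)
        lo_keys, hi_keys = {key(r) for r in lo}, {key(r) for r in hi}
        assert lo_keys <= hi_keys
        assert len(hi) > len(lo)

    def test_severity_always_critical_station(self, config):
        """A station whose severity spec is DISC(0,1,1,2) (the ICU) only
        generates critical requests."""
        reqs = generate_arrivals(
            config.schedule, config.routing, config.specs, 1.0, 30,
            np.random.default_rng(np.random.SeedSequence(1)),
        )
        icu = [r for r in reqs if r.origin == 15]
        assert icu and all(r.severity == CRITICAL for r in icu)
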