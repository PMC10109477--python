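"""Shared fixtures: default configuration and a hand-traceable tiny network."""

from __future__ import annotations

import numpy as np
import pytest

from ihtsim import (
    ArrivalSchedule,
    ModelConfig,
    NetworkConfig,
    RoutingRule,
    Station,
    StationSpecs,
    default_config,
    parse_expression,
)


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return default_config()


@pytest.fixture(scope="session")
def table_expressions(config) -> list[str]:
    """Every distribution expression in the packaged default (severity,
    operated time, vehicle for each of the 19 spec-bearing stations)."""
    out = []
    for sp in config.specs.values():
        out.extend([sp.severity.source_text, sp.operated_time.source_text,
                    sp.vehicle.source_text])
    return out


def make_tiny_config(
    *,
    d_base_origin: float = 2.0,
    d_origin_dest: float = 4.0,
    d_dest_base: float = 3.0,
    d_dest_origin: float = 1.5,
    two_leg: bool = False,
) -> ModelConfig:
    """A 4-station network: base(1), origin(2), destination(3), imaging(4).

    All distribution specs are constants so event times can be traced by
    hand; arrival rates are zero (tests inject explicit requests).
    """
    stations = [
        Station(1, "Base", True),
        Station(2, "Origin", False),
        Station(3, "Dest", False),
        Station(4, "Imaging", False),
    ]
    t = np.zeros((4, 4))
    pairs = {
        (1, 2): d_base_origin, (2, 1): d_base_origin,
        (2, 3): d_origin_dest, (3, 2): d_dest_origin,
        (3, 1): d_dest_base, (1, 3): d_dest_base,
        (2, 4): 1.0, (4, 2): 1.0, (1, 4): 2.5, (4, 1): 2.5,
        (3, 4): 2.0, (4, 3): 2.0,
    }
    for (a, b), v in pairs.items():
        t[a - 1, b - 1] = v
    network = NetworkConfig(stations, t)
    schedule = ArrivalSchedule({(2, "M"): 0.0})
    routing = RoutingRule(
        {2: {3: 1.0}},
        {2: 1.0} if two_leg else {},
        {2: {4: 1.0}} if two_leg else {},
    )
    const = lambda v: parse_expression(f"CONST({v})")
    specs = {
        2: StationSpecs(const(1), parse_expression("CONST(10)"), const(1)),
        4: StationSpecs(const(1), parse_expression("CONST(3)"), const(1)),
    }
    return ModelConfig(network, schedule, routing, specs)


@pytest.fixture
def tiny_config() -> ModelConfig:
    return make_tiny_config()
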