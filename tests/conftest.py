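"""Shared fixtures: tiny synthetic tissue tables and chain builders.

All test networks are generated programmatically; the packaged anatomical
table is exercised only by a few end-to-end tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

from sonoline import SourcePulse, TissueTable, build_network


def make_table(rows):
    """Build a TissueTable from (name, density, speed, length) tuples."""
    return TissueTable(
        pd.DataFrame(rows, columns=["name", "density_kg_m3", "speed_m_s", "length_m"])
    )


def chain_model(impedances, delays, speed=1.0):
    """Linear chain with prescribed impedances (via density) and delays (via length).

    With speed 1 m/s, density equals impedance and length equals delay in
    seconds, which keeps test parametrisation readable.
    """
    rows = [
        (f"tissue{i}", z, speed, tau * speed)
        for i, (z, tau) in enumerate(zip(impedances, delays))
    ]
    table = make_table(rows)
    n = len(rows)
    spec = {
        "source": "n0",
        "lines": [
            {"id": f"T{i + 1}", "tissue": f"tissue{i}", "from": f"n{i}", "to": f"n{i + 1}"}
            for i in range(n)
        ],
        "terminal_labels": {f"T{n}": "chain end"},
    }
    return build_network(table, spec)


def star_model(trunk_z, branch_zs, trunk_delay=5e-7, branch_delay=5e-7):
    """One trunk feeding N parallel branches, all ending in matched loads."""
    rows = [("trunk", trunk_z, 1.0, trunk_delay)] + [
        (f"branch{i}", z, 1.0, branch_delay) for i, z in enumerate(branch_zs)
    ]
    table = make_table(rows)
    lines = [{"id": "T1", "tissue": "trunk", "from": "root", "to": "hub"}] + [
        {"id": f"T{i + 2}", "tissue": f"branch{i}", "from": "hub", "to": f"leaf{i}"}
        for i in range(len(branch_zs))
    ]
    spec = {
        "source": "root",
        "lines": lines,
        "terminal_labels": {f"T{i + 2}": f"branch {i}" for i in range(len(branch_zs))},
    }
    return build_network(table, spec)


@pytest.fixture
def unit_source():
    return SourcePulse(amplitude=1.0, period=500e-6, width=1e-6)


@pytest.fixture
def toy_table():
    """Three water-like layers."""
    return make_table(
        [
            ("layer_a", 1000.0, 1480.0, 0.001),
            ("layer_b", 1050.0, 1540.0, 0.002),
            ("layer_c", 1100.0, 1580.0, 0.001),
        ]
    )
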