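"""Shared small-network fixtures for the test suite."""

from __future__ import annotations

import pytest

from dialectsim import SimParams, make_topology


@pytest.fixture
def pair_topology():
    """Two connected nodes A-B, unit populations and distance."""
    return make_topology([("A", 1.0), ("B", 1.0)], [("A", "B", 1.0)])


@pytest.fixture
def triangle_topology():
    """Three mutually connected nodes with distinct populations."""
    return make_topology(
        [("A", 1.0), ("B", 2.0), ("C", 4.0)],
        [("A", "B", 1.0), ("B", "C", 2.0), ("A", "C", 1.0)],
    )


@pytest.fixture
def quick_params():
    """Small, fast parameter set for dynamics tests."""
    return SimParams(s=2.0, b=0.5, d=3.0, T=50, n_concepts=3, seed=7)
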