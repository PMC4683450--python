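"""Shared fixtures: exact small-chain tables and analytic toys.

Everything is generated at test time; nothing is read from disk.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from slitperm import ModelParams, enumerate_dos, two_state_table


@functools.lru_cache(maxsize=None)
def exact_table(nm: int, eps_bend: float = 0.0, slit_height: int | None = None):
    """Memoized exact enumeration (tables are reused across many tests)."""
    return enumerate_dos(ModelParams(nm, eps_bend, slit_height))


@pytest.fixture(scope="session")
def nm4_bulk():
    """The Nm=4 flexible bulk table: g(0)=126, g(1)=24."""
    return exact_table(4)


@pytest.fixture(scope="session")
def toy_two_state():
    """Two-level system g(0)=e^10, g(10)=1: eps* = 1 exactly."""
    return two_state_table(10.0, 10)


def assert_tables_equal(a, b):
    np.testing.assert_array_equal(a.nc, b.nc)
    np.testing.assert_allclose(a.log_g, b.log_g, rtol=1e-12, atol=1e-12)
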