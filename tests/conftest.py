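"""Shared fixtures and the exhaustive allocation oracle.

The oracle enumerates every integer land allocation (zone areas in
whole units) under national share bounds with integer right-hand
sides.  The allocation constraint matrix has transportation structure
and is totally unimodular, so for integer data the continuous LP
optimum coincides with the best integer allocation — which makes
exhaustive enumeration an exact, independent check of the LP.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from nutriscen.synthetic_data import BaselineBundle, GeneratorConfig, generate_baseline


def brute_force_allocation(
    yields: np.ndarray, zone_areas: np.ndarray,
    min_units: np.ndarray, max_units: np.ndarray,
) -> float:
    """Best objective over all integer allocations.

    ``yields`` is zones x crops; ``zone_areas`` integer units per zone;
    ``min_units``/``max_units`` integer national bounds per crop.
    Returns -inf if no allocation is feasible.
    """
    nz, nc = yields.shape

    def zone_options(area: int):
        # All ways to split <= `area` units across crops.
        for total in range(area + 1):
            for cut in itertools.combinations(range(total + nc - 1), nc - 1):
                parts = []
                prev = -1
                for c in cut:
                    parts.append(c - prev - 1)
                    prev = c
                parts.append(total + nc - 1 - prev - 1)
                yield tuple(parts)

    best = -np.inf
    options = [list(zone_options(int(a))) for a in zone_areas]
    for combo in itertools.product(*options):
        totals = np.sum(combo, axis=0)
        if np.any(totals < min_units) or np.any(totals > max_units):
            continue
        obj = float(np.sum(np.array(combo) * yields))
        best = max(best, obj)
    return best


def random_allocation_instance(rng: np.random.Generator):
    """A small random instance with integer areas and integer bounds."""
    nz = int(rng.integers(2, 5))
    nc = int(rng.integers(2, 4))
    areas = rng.integers(1, 4, size=nz)
    total = int(areas.sum())
    yields = rng.uniform(0.2, 5.0, size=(nz, nc))
    max_units = rng.integers(1, total + 1, size=nc)
    # Keep minimum shares jointly feasible.
    min_units = np.minimum(rng.integers(0, 2, size=nc), max_units)
    while min_units.sum() > total:
        min_units[np.argmax(min_units)] -= 1
    return yields, areas, min_units, max_units


def as_share_bounds(min_units, max_units, total):
    return {
        f"crop{j}": (min_units[j] / total, max_units[j] / total)
        for j in range(len(min_units))
    }


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=123, n_commodities=8, n_zones=4)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> BaselineBundle:
    return generate_baseline(small_config)


@pytest.fixture(scope="session")
def default_bundle() -> BaselineBundle:
    return generate_baseline(GeneratorConfig(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a, b)
        return True
    except AssertionError:
        return False
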