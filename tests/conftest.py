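"""Shared fixtures: cached year-simulations reused across the suite.

Year-long chemostat runs dominate the suite's cost, and several tests
interrogate the same operating points, so a session-scoped memoizing runner
keeps the wall time down without any test depending on another.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import phytopond as pp

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from phytopond.chemostat import OperatingPoint, simulate_year
from phytopond.physiology import MediumSpec

#: time step used throughout the suite (days); fast yet inside the
#: integrator's validated convergence range.
DT = 0.005


@pytest.fixture(scope="session")
def run():
    """Memoized (strain, lat, D, tau, multiplier) -> Trajectory runner."""
    cache: dict[tuple, object] = {}

    def _run(strain: str, lat: float, D: float, tau: float, mult: float = 1.0,
             dt: float = DT):
        key = (strain, lat, D, tau, mult, dt)
        if key not in cache:
            p = pp.STRAIN_PRESETS[strain]
            op = OperatingPoint(lat, D, tau, MediumSpec.f2(mult))
            cache[key] = simulate_year(p, op, dt=dt)
        return cache[key]

    return _run


@pytest.fixture(scope="session")
def summarize(run):
    """Memoized annual summary for an operating point."""

    def _s(strain: str, lat: float, D: float, tau: float, mult: float = 1.0,
           dt: float = DT):
        return pp.annual_mean(run(strain, lat, D, tau, mult, dt))

    return _s


@pytest.fixture(scope="session")
def dilution_curves(summarize):
    """AP(D) at f/2 and AXP(D) at f/4 for all four strains (lat 45, tau 0.1).

    A scaled-down version of the full dilution scan: D step 0.04.
    """
    grid = np.round(np.arange(0.04, 0.46, 0.04), 3)
    out = {}
    for name in ("XS", "S", "M", "F"):
        ap = np.array([summarize(name, 45.0, D, 0.1, 1.0).AP for D in grid])
        axp = np.array([summarize(name, 45.0, D, 0.1, 0.5).AXP for D in grid])
        out[name] = {"D": grid, "AP": ap, "AXP": axp}
    return out


@pytest.fixture(scope="session")
def latitude_best_ap(summarize):
    """Best annual AP over a coarse D grid at latitudes 0 and 65 (f/2, tau 0.1)."""
    grid = np.round(np.arange(0.04, 0.38, 0.04), 3)
    out = {}
    for name in ("S", "F"):
        for lat in (0.0, 65.0):
            out[(name, lat)] = max(summarize(name, lat, D, 0.1, 1.0).AP for D in grid)
    return out
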