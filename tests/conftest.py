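"""Shared fixtures: synthetic decays and fitted noiseless profile series.

The two fitted series (PG- and FBS-substrate scenarios) are expensive
(full 256-row, 256-echo profiles through model selection), so they are
built once per session and shared by the fitting, front-detection and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from relaxstack import (
    AcquisitionGrid,
    build_scenario,
    extract_profile,
    fit_profile_series,
    label_components,
    synthesize_stack,
)


@pytest.fixture(scope="session")
def grid() -> AcquisitionGrid:
    return AcquisitionGrid()


def synth_decay(grid: AcquisitionGrid, components, y0: float = 0.0) -> np.ndarray:
    """Noiseless multi-exponential decay from (amplitude, t2_ms) pairs."""
    t = grid.echo_times_ms
    out = np.full(len(t), float(y0))
    for amp, t2 in components:
        out += amp * np.exp(-t / t2)
    return out


@pytest.fixture(scope="session")
def m8_pg_fitted(grid):
    """Noiseless M8/PG scenario fitted at 15/60/120 min (scenario, series)."""
    scenario = build_scenario("M8_PG")
    profiles = [
        extract_profile(synthesize_stack(scenario, grid, t=t), origin_row=scenario.origin_row)
        for t in (15, 60, 120)
    ]
    series = fit_profile_series(profiles, layers=scenario.layers)
    series = label_components(series, substrate_medium="PG")
    return scenario, series


@pytest.fixture(scope="session")
def m8_fbs_fitted(grid):
    """Noiseless M8/FBS scenario fitted at 15/30/45/60/120 min."""
    scenario = build_scenario("M8_FBS")
    profiles = [
        extract_profile(synthesize_stack(scenario, grid, t=t), origin_row=scenario.origin_row)
        for t in (15, 30, 45, 60, 120)
    ]
    series = fit_profile_series(profiles, layers=scenario.layers)
    series = label_components(series, substrate_medium="FBS")
    return scenario, series
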