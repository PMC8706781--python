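"""Front detection, tracking, and temporal change metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxstack import (
    build_scenario,
    detect_component_fronts,
    detect_trend_fronts,
    extract_profile,
    fit_profile_series,
    flattening_time,
    label_components,
    percent_change,
    synthesize_stack,
    track_fronts,
)
from relaxstack.fronts import ChangeMetric, FrontDetection
from relaxstack.multiexp import ParametricProfileSeries
from relaxstack.phantom_sim import NoiseSpec
from relaxstack.stack_io import ProfileStack


def make_series(L, counts=None, values=None, label="water_dressing", t=15.0,
                layers=None):
    """Hand-build a one-time-point series table for detector unit tests."""
    rows = []
    for i, x in enumerate(L):
        n = 1 if counts is None else int(counts[i])
        v = 50.0 if values is None else float(values[i])
        for j in range(n):
            rows.append(
                {"t_min": t, "L_mm": float(x), "n": n, "comp_idx": j,
                 "label": label if j == 0 else f"extra{j}", "A": 100.0,
                 "T2_ms": v, "y0": 0.0, "r2": 1.0, "flags": ""}
            )
    return ParametricProfileSeries(
        pd.DataFrame(rows), layers or {"dressing": (0.0, 6.0)}
    )


class TestComponentFronts:
    def test_uniform_profile_no_fronts(self):
        L = np.arange(0.05, 6.0, 0.1)
        series = make_series(L, counts=np.full(len(L), 2))
        assert detect_component_fronts(series, 15.0) == []

    def test_single_pixel_blip_ignored_by_persistence(self):
        L = np.arange(0.05, 6.0, 0.1)
        counts = np.ones(len(L), int)
        counts[20] = 2  # isolated: persists for 1 px < default m=3
        series = make_series(L, counts=counts)
        assert detect_component_fronts(series, 15.0) == []

    def test_persistent_change_detected_at_midpoint(self):
        L = np.arange(0.05, 6.0, 0.1)
        counts = np.where(L < 3.0, 2, 1)
        series = make_series(L, counts=counts)
        dets = detect_component_fronts(series, 15.0)
        assert len(dets) == 1
        d = dets[0]
        assert d.kind == "component_disappearance"
        assert d.L_mm == pytest.approx(3.0, abs=0.1)
        assert d.uncertainty_mm >= 0.1

    def test_noiseless_pg_scenario_fronts_within_one_pixel(self, m8_pg_fitted, grid):
        """Both canned fronts (dressing 4.0 mm, substrate 7.4 mm at 15 min)
        are recovered within one pixel, with no spurious detections."""
        scenario, series = m8_pg_fitted
        pix = grid.pixel_mm[0]
        for t in (15, 60, 120):
            dets = detect_component_fronts(series, t)
            assert len(dets) == 2  # precision = recall = 1
            by_layer = {d.layer: d for d in dets}
            for fr_name, layer in [("dressing_front", "dressing"),
                                   ("substrate_front", "substrate")]:
                truth = scenario.front_map[fr_name].position(t)
                assert abs(by_layer[layer].L_mm - truth) <= pix

    def test_noise_robustness_substrate_front(self, grid):
        """At SNR 100, the substrate front position error stays within two
        pixels (Monte Carlo; reduced to the substrate window and 6 seeds
        to keep the suite fast)."""
        scenario = build_scenario("M8_PG")
        truth = scenario.front_map["substrate_front"].position(60)
        pix = grid.pixel_mm[0]
        errors = []
        for seed in range(6):
            noise = NoiseSpec("gaussian", sigma=250.0 / 100, seed=seed)
            stack = synthesize_stack(scenario, grid, t=60, noise=noise)
            prof = extract_profile(stack, origin_row=scenario.origin_row)
            mask = (prof.positions_mm >= 6.0) & (prof.positions_mm <= 11.5)
            sub = ProfileStack(prof.signal[mask], prof.positions_mm[mask],
                               prof.segment, prof.grid, prof.time_point_min)
            series = fit_profile_series([sub], layers={"substrate": (6.0, 12.0)})
            series = label_components(series, substrate_medium="PG",
                                      layers={"substrate": (6.0, 12.0)})
            dets = detect_component_fronts(series, 60, layers=("substrate",))
            assert dets, f"front lost at seed {seed}"
            errors.append(min(abs(d.L_mm - truth) for d in dets))
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse <= 2 * pix


class TestTrendFronts:
    def test_strictly_linear_profile_no_front(self):
        L = np.arange(0.05, 6.0, 0.1)
        series = make_series(L, values=40.0 + 3.0 * L)
        assert detect_trend_fronts(series, 15.0) == []

    def test_step_profile_breakpoint_matches_bruteforce(self):
        """Step of height h: detector breakpoint equals the exhaustive
        two-segment least-squares oracle, at the step."""
        L = np.arange(0.05, 6.0, 0.1)
        values = np.where(L < 4.0, 50.0, 80.0)
        series = make_series(L, values=values)
        dets = detect_trend_fronts(series, 15.0)
        assert len(dets) == 1
        # independent oracle: try every breakpoint with np.polyfit loops
        best_k, best_rss = None, np.inf
        for k in range(2, len(L) - 2):
            r1 = np.polyfit(L[: k + 1], values[: k + 1], 1, full=True)[1]
            r2 = np.polyfit(L[k:], values[k:], 1, full=True)[1]
            rss = float(r1[0] if len(r1) else 0.0) + float(r2[0] if len(r2) else 0.0)
            if rss < best_rss:
                best_k, best_rss = k, rss
        assert dets[0].L_mm == pytest.approx(L[best_k], abs=0.15)
        assert abs(dets[0].L_mm - 4.0) <= 0.15

    def test_fbs_transient_zone_front_within_two_pixels(self, m8_fbs_fitted, grid):
        """The transient zone of rising water T2 begins at 5.7 mm."""
        scenario, series = m8_fbs_fitted
        dets = detect_trend_fronts(series, 15)
        assert len(dets) == 1
        assert abs(dets[0].L_mm - 5.7) <= 2 * grid.pixel_mm[0]


class TestTracking:
    def _det(self, kind, t, L, layer="substrate"):
        return FrontDetection(kind, t, L, 0.094, layer)

    def test_canned_trajectory_direction_into_substrate(self):
        dets = [self._det("component_appearance", t, L)
                for t, L in [(15, 7.4), (60, 8.4), (120, 9.3)]]
        trajs = track_fronts(dets)
        assert len(trajs) == 1
        assert trajs[0].direction == "into_substrate"
        assert trajs[0].samples == [(15, 7.4), (60, 8.4), (120, 9.3)]

    def test_two_simultaneous_fronts_beyond_gate_split(self):
        dets = [self._det("component_appearance", 15, 7.0),
                self._det("component_appearance", 15, 10.5),
                self._det("component_appearance", 60, 7.5),
                self._det("component_appearance", 60, 11.0)]
        trajs = track_fronts(dets, gate_mm=2.0)
        assert len(trajs) == 2

    def test_vanishing_front_terminates_trajectory(self, m8_fbs_fitted):
        """PG-depletion front exists at 15 min, the PG pool is gone by 30:
        its trajectory must not extend past 30 min."""
        _, series = m8_fbs_fitted
        dets = []
        for t in (15, 30, 45, 60, 120):
            dets.extend(detect_component_fronts(series, t))
        trajs = track_fronts(dets)
        dress = [tr for tr in trajs if tr.layer == "dressing"]
        assert len(dress) == 1
        assert dress[0].times_min.max() <= 30

    def test_scenario_trajectories_monotone(self, m8_pg_fitted):
        scenario, series = m8_pg_fitted
        dets = []
        for t in (15, 60, 120):
            dets.extend(detect_component_fronts(series, t))
        trajs = track_fronts(dets)
        assert len(trajs) == 2
        for tr in trajs:
            diffs = np.diff(tr.positions_mm)
            if tr.layer == "substrate":
                assert np.all(diffs > 0) and tr.direction == "into_substrate"
            else:
                assert np.all(diffs < 0) and tr.direction == "toward_dressing_top"


class TestChangeMetrics:
    def test_fbs_substrate_water_reduction_23_percent(self, m8_fbs_fitted):
        _, series = m8_fbs_fitted
        m = percent_change(series, "T2_ms", "water_substrate", "substrate", 15, 120)
        assert m.value_t0 == pytest.approx(133.0, rel=1e-3)
        assert m.value_t1 == pytest.approx(103.0, rel=1e-3)
        assert m.relative_change_percent == pytest.approx(-22.556, abs=0.05)
        assert m.rounded_percent == 23

    def test_equal_values_zero_change(self):
        L = np.arange(0.05, 6.0, 0.1)
        s1 = make_series(L, values=np.full(len(L), 70.0), t=15.0)
        s2 = make_series(L, values=np.full(len(L), 70.0), t=60.0)
        series = ParametricProfileSeries(
            pd.concat([s1.table, s2.table]), s1.layers
        )
        m = percent_change(series, "T2_ms", "water_dressing", "dressing", 15, 60)
        assert m.relative_change_percent == 0.0

    def test_absent_parameter_raises(self, m8_fbs_fitted):
        _, series = m8_fbs_fitted
        with pytest.raises(ValueError):
            percent_change(series, "T2_ms", "pg_long_substrate", "substrate", 15, 120)

    @given(a=st.floats(1.0, 500.0), b=st.floats(1.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_identity(self, a, b):
        """metric(a,b) = -metric(b,a) * b/a (exchange of endpoints changes
        the base): (b-a)/a == -((a-b)/b) * (b/a)."""
        m_ab = ChangeMetric("p", "l", "d", 0, 1, a, b).relative_change_percent
        m_ba = ChangeMetric("p", "l", "d", 0, 1, b, a).relative_change_percent
        assert m_ab == pytest.approx(-m_ba * b / a, rel=1e-9)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ChangeMetric("p", "l", "d", 0, 1, 0.0, 10.0)


class TestFlattening:
    def test_fbs_dressing_flattens_at_one_hour(self, m8_fbs_fitted):
        _, series = m8_fbs_fitted
        assert flattening_time(series) == 60.0

    def test_already_flat_series_first_time_point(self):
        L = np.arange(0.05, 6.0, 0.1)
        tables = [make_series(L, values=np.full(len(L), 70.0), t=t).table
                  for t in (15.0, 30.0)]
        series = ParametricProfileSeries(pd.concat(tables), {"dressing": (0.0, 6.0)})
        assert flattening_time(series) == 15.0

    def test_never_flattening_series_none(self):
        L = np.arange(0.05, 6.0, 0.1)
        tables = [make_series(L, values=50 + 20 * L, t=t).table for t in (15.0, 30.0)]
        series = ParametricProfileSeries(pd.concat(tables), {"dressing": (0.0, 6.0)})
        assert flattening_time(series) is None
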