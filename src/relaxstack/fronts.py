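"""Moving-front detection and temporal change metrics on parametric profiles.

Two operational front detectors are provided (profiles only show fronts
as sharp features; no algorithm is canonical):

* component-count fronts: positions where the fitted component count
  changes between adjacent pixels and the new count persists for at
  least ``persistence`` pixels;
* trend fronts: change points of a parameter-vs-L profile, located by an
  exact two-segment least-squares scan over all breakpoints, reported
  where the slope changes sign or by a configurable factor.

Detections are associated across time points by gated nearest-neighbor
matching into trajectories, whose direction (toward the dressing top or
deeper into the substrate) summarizes the transport.  Temporal change
metrics (signed percent change of a layer-averaged parameter, and the
time at which a layer's spatial profile flattens) quantify the approach
to steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .multiexp import ParametricProfileSeries

__all__ = [
    "FrontDetection",
    "FrontTrajectory",
    "ChangeMetric",
    "detect_component_fronts",
    "detect_trend_fronts",
    "track_fronts",
    "percent_change",
    "flattening_time",
]


@dataclass(frozen=True)
class FrontDetection:
    """One detected front at one time point."""

    kind: str  # component_appearance | component_disappearance | trend_change
    time_point_min: float
    L_mm: float
    uncertainty_mm: float
    layer: str
    evidence: dict = field(default_factory=dict, hash=False, compare=False)


@dataclass
class FrontTrajectory:
    kind: str
    layer: str
    samples: list[tuple[float, float]]  # ordered (t_min, L_mm)
    direction: str = "stationary"  # toward_dressing_top | into_substrate | stationary

    def __post_init__(self) -> None:
        ts = [s[0] for s in self.samples]
        if any(t1 <= t0 for t0, t1 in zip(ts, ts[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples])

    @property
    def times_min(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])


@dataclass(frozen=True)
class ChangeMetric:
    """Signed relative change of a parameter between two time points."""

    parameter: str
    label: str
    layer: str
    t0_min: float
    t1_min: float
    value_t0: float
    value_t1: float

    def __post_init__(self) -> None:
        if self.value_t0 <= 0:
            raise ValueError("value_t0 must be positive")

    @property
    def relative_change_percent(self) -> float:
        return 100.0 * (self.value_t1 - self.value_t0) / self.value_t0

    @property
    def rounded_percent(self) -> int:
        """Magnitude rounded to whole percent, for presentation."""
        return round(abs(self.relative_change_percent))


def _pixel_mm(positions: np.ndarray) -> float:
    return float(np.median(np.diff(positions))) if len(positions) > 1 else 0.0


def detect_component_fronts(
    series: ParametricProfileSeries,
    t: float,
    persistence: int = 3,
    layers: tuple[str, ...] = ("dressing", "substrate"),
) -> list[FrontDetection]:
    """Scan the component-count profile for persistent count changes.

    A boundary between adjacent pixels counts as a front only when the
    count is constant for at least ``persistence`` pixels on each side
    (or up to the layer edge, if nearer).  The front position is the
    midpoint between the two pixel centers; the uncertainty is one pixel.
    kind reflects the scan direction (increasing L): a component gained
    across the boundary is an appearance, one lost a disappearance.
    """
    detections: list[FrontDetection] = []
    for layer in layers:
        if layer not in series.layers:
            continue
        Ls, ns = series.component_count(t, layer)
        if len(Ls) < 2:
            continue
        pix = _pixel_mm(Ls)
        # label sets per position, to name what appeared/disappeared
        df = series.table[np.isclose(series.table["t_min"], t)]
        lab = df.groupby("L_mm")["label"].agg(lambda s: frozenset(s))
        for i in range(len(Ls) - 1):
            if ns[i] == ns[i + 1] or ns[i] == 0 or ns[i + 1] == 0:
                continue
            left = ns[max(0, i - persistence + 1): i + 1]
            right = ns[i + 1: i + 1 + persistence]
            if not (np.all(left == ns[i]) and np.all(right == ns[i + 1])):
                continue
            kind = (
                "component_appearance" if ns[i + 1] > ns[i] else "component_disappearance"
            )
            before = lab.get(Ls[i], frozenset())
            after = lab.get(Ls[i + 1], frozenset())
            changed = sorted((after - before) | (before - after))
            detections.append(
                FrontDetection(
                    kind=kind,
                    time_point_min=t,
                    L_mm=float(0.5 * (Ls[i] + Ls[i + 1])),
                    uncertainty_mm=max(pix, 1e-9),
                    layer=layer,
                    evidence={
                        "parameter": "component_count",
                        "n_before": int(ns[i]),
                        "n_after": int(ns[i + 1]),
                        "changed_labels": changed,
                    },
                )
            )
    return detections


def _two_segment_scan(L: np.ndarray, p: np.ndarray):
    """Exact least-squares two-segment scan: best breakpoint and slopes."""
    n = len(L)
    best = None
    for k in range(2, n - 2):  # each segment needs >= 3 points
        c1 = np.polyfit(L[: k + 1], p[: k + 1], 1)
        c2 = np.polyfit(L[k:], p[k:], 1)
        rss = float(
            np.sum((np.polyval(c1, L[: k + 1]) - p[: k + 1]) ** 2)
            + np.sum((np.polyval(c2, L[k:]) - p[k:]) ** 2)
        )
        if best is None or rss < best[0]:
            best = (rss, k, c1[0], c2[0])
    return best


def detect_trend_fronts(
    series: ParametricProfileSeries,
    t: float,
    parameter: str = "T2_ms",
    label: str = "water_dressing",
    layer: str = "dressing",
    slope_factor: float = 3.0,
    min_improvement: float = 0.5,
) -> list[FrontDetection]:
    """Locate a change point of a labeled parameter profile within a layer.

    A two-segment least-squares fit over every admissible breakpoint
    finds the best split; a front is reported when the split explains at
    least ``min_improvement`` of the single-line residual and the slope
    changes sign or in magnitude by ``slope_factor``.  Uncertainty is
    two pixels (breakpoint granularity plus segment-end ambiguity).
    """
    Ls, ps = series.parameter_profile(t, label, parameter, layer)
    mask = np.isfinite(ps)
    Ls, ps = Ls[mask], ps[mask]
    if len(Ls) < 8:
        return []
    pix = _pixel_mm(Ls)
    c_all = np.polyfit(Ls, ps, 1)
    rss_one = float(np.sum((np.polyval(c_all, Ls) - ps) ** 2))
    scale = float(np.ptp(ps))
    if scale <= 0 or rss_one <= (1e-9 * scale) ** 2 * len(Ls):
        return []  # profile is a single line (or constant): no trend change
    best = _two_segment_scan(Ls, ps)
    if best is None:
        return []
    rss_two, k, s1, s2 = best
    improvement = 1.0 - rss_two / rss_one
    if improvement < min_improvement:
        return []
    slope_eps = 0.01 * scale / max(Ls[-1] - Ls[0], 1e-9)
    sign_change = (s1 < -slope_eps < slope_eps < s2) or (s2 < -slope_eps < slope_eps < s1)
    a1, a2 = abs(s1), abs(s2)
    ratio_change = max(a1, a2) >= slope_factor * max(min(a1, a2), slope_eps)
    if not (sign_change or ratio_change):
        return []
    return [
        FrontDetection(
            kind="trend_change",
            time_point_min=t,
            L_mm=float(Ls[k]),
            uncertainty_mm=max(2 * pix, 1e-9),
            layer=layer,
            evidence={
                "parameter": parameter,
                "label": label,
                "slope_before": float(s1),
                "slope_after": float(s2),
                "improvement": float(improvement),
            },
        )
    ]


def track_fronts(
    detections: list[FrontDetection],
    gate_mm: float = 2.0,
) -> list[FrontTrajectory]:
    """Associate per-time-point detections into trajectories.

    Nearest-neighbor matching across consecutive time points within a
    gating distance, restricted to the same kind and layer; unmatched
    detections start (or end) trajectories.  Direction is inferred from
    the net displacement along L.
    """
    groups: dict[tuple[str, str], list[FrontDetection]] = {}
    for d in detections:
        groups.setdefault((d.kind, d.layer), []).append(d)
    trajectories: list[FrontTrajectory] = []
    for (kind, layer), dets in groups.items():
        by_time: dict[float, list[FrontDetection]] = {}
        for d in dets:
            by_time.setdefault(d.time_point_min, []).append(d)
        times = sorted(by_time)
        open_tracks: list[list[tuple[float, float]]] = []
        for t in times:
            current = list(by_time[t])
            claimed = [False] * len(current)
            for track in open_tracks:
                last_L = track[-1][1]
                cands = [
                    (abs(d.L_mm - last_L), j)
                    for j, d in enumerate(current)
                    if not claimed[j] and abs(d.L_mm - last_L) <= gate_mm
                ]
                if cands:
                    _, j = min(cands)
                    claimed[j] = True
                    track.append((t, current[j].L_mm))
            for j, d in enumerate(current):
                if not claimed[j]:
                    open_tracks.append([(t, d.L_mm)])
        for track in open_tracks:
            net = track[-1][1] - track[0][1]
            if abs(net) < 1e-9:
                direction = "stationary"
            else:
                direction = "into_substrate" if net > 0 else "toward_dressing_top"
            trajectories.append(
                FrontTrajectory(kind=kind, layer=layer, samples=track, direction=direction)
            )
    return trajectories


def _layer_value(
    series: ParametricProfileSeries,
    parameter: str,
    label: str,
    layer: str,
    t: float,
    at_L: float | None,
) -> float:
    Ls, ps = series.parameter_profile(t, label, parameter, layer)
    ps = ps[np.isfinite(ps)] if at_L is None else ps[np.isclose(Ls, at_L)]
    if len(ps) == 0:
        raise ValueError(
            f"parameter {parameter!r}/{label!r} absent in layer {layer!r} at t={t}"
        )
    return float(np.mean(ps))


def percent_change(
    series: ParametricProfileSeries,
    parameter: str,
    label: str,
    layer: str,
    t0: float,
    t1: float,
    at_L: float | None = None,
) -> ChangeMetric:
    """Signed relative change of a layer-averaged parameter, t0 -> t1.

    The parameter is spatially averaged over the layer (or taken at a
    stated L); rounding happens only at presentation
    (:attr:`ChangeMetric.rounded_percent`).
    """
    v0 = _layer_value(series, parameter, label, layer, t0, at_L)
    v1 = _layer_value(series, parameter, label, layer, t1, at_L)
    return ChangeMetric(
        parameter=parameter, label=label, layer=layer,
        t0_min=t0, t1_min=t1, value_t0=v0, value_t1=v1,
    )


def flattening_time(
    series: ParametricProfileSeries,
    parameter: str = "T2_ms",
    label: str = "water_dressing",
    layer: str = "dressing",
    threshold: float = 0.05,
) -> float | None:
    """First time point after which the layer's spatial profile stays flat.

    Flat means the spatial coefficient of variation of the parameter
    within the layer is below ``threshold`` (default 5%) at that time
    point and at every later sampled one; None if that never happens.
    """
    times = series.time_points
    cvs = []
    for t in times:
        _, ps = series.parameter_profile(t, label, parameter, layer)
        ps = ps[np.isfinite(ps)]
        if len(ps) == 0 or np.mean(ps) <= 0:
            cvs.append(np.inf)
        else:
            cvs.append(float(np.std(ps) / np.mean(ps)))
    flat = np.array(cvs) < threshold
    for i, t in enumerate(times):
        if np.all(flat[i:]):
            return float(t)
    return None
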