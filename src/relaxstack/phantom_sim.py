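"""Synthetic MSME phantoms of a layered wound-dressing stack.

The phantom is a 1D-layered object imaged along the stack axis L (mm):
a hydrogel dressing occupies L in [0, 6), a wetted sponge substrate
L in [6, 12], and a water-filled reference compartment sits above the
dressing (negative L).  Each location carries 1-3 exponential signal
components (water / propylene-glycol proton pools in different
environments); a pixel's echo-train intensity is

    f(t) = y0 + sum_i A_i * exp(-t / T2_i)

evaluated on the acquisition's echo grid.  Component fields evolve in
time by piecewise-linear interpolation between sparse anchors, and
components appear/disappear across sharp moving fronts, so the phantom
encodes bidirectional mass transport between dressing and substrate
without solving any transport PDE.

Canned scenarios
----------------
``M8_FBS`` / ``M8L_FBS``
    Dressing on a serum-wetted sponge: PG leaves the dressing (depletion
    front, fully gone by 30 min), water enters (dressing water T2 rises
    53 -> 75 -> 87 ms for M8), a transient zone of elevated water T2
    starts at L = 5.7 mm, substrate water T2 falls 133 -> 103 ms (M8) /
    134 -> 109 ms (M8_L), and profiles flatten by ~1 h.
``M8_PG`` / ``M8L_PG``
    Dressing on a PG-wetted sponge: a third (intermediate, ~50 ms)
    component appears around the contact plane; the dressing front moves
    toward the top (4.0/3.5/3.0 mm at 15/60/120 min for M8) while the
    substrate front moves deeper (7.4/8.4/9.3 mm); the M8 system ends at
    a 13/50/250 ms triplet at 48 h, M8_L at a ~60/~300 ms pair.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionGrid

__all__ = [
    "AcquisitionGrid",
    "ExpComponent",
    "FrontTruth",
    "NoiseSpec",
    "ComponentRule",
    "PhantomScenario",
    "SCENARIO_NAMES",
    "build_scenario",
    "truth_components",
    "synthesize_stack",
    "export_truth",
    "export_fronts",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

COMPONENT_LABELS = (
    "water_dressing",
    "pg_dressing",
    "water_substrate",
    "pg_short_substrate",
    "pg_long_substrate",
    "intermediate",
    "reference",
)

SCENARIO_NAMES = ("M8_FBS", "M8L_FBS", "M8_PG", "M8L_PG")


@dataclass(frozen=True)
class ExpComponent:
    """One exponential signal component: amplitude A (a.u.) and T2 (ms)."""

    amplitude: float
    t2_ms: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.t2_ms <= 0:
            raise ValueError("t2_ms must be positive")


@dataclass
class FrontTruth:
    """Ground-truth trajectory of one moving front.

    positions maps time (min) -> L (mm); between anchors the position is
    linearly interpolated, outside the anchored span it is held constant.
    Positions must be monotone in time (the front moves one way).
    """

    name: str
    kind: str  # component_appearance | component_disappearance | trend_change
    positions: dict[float, float]
    layer: str = "dressing"
    direction: str = "toward_dressing_top"

    def __post_init__(self) -> None:
        if self.kind not in (
            "component_appearance",
            "component_disappearance",
            "trend_change",
        ):
            raise ValueError(f"unknown front kind {self.kind!r}")
        ts = sorted(self.positions)
        ls = [self.positions[t] for t in ts]
        diffs = np.diff(ls)
        if len(diffs) and not (np.all(diffs >= 0) or np.all(diffs <= 0)):
            raise ValueError(f"front {self.name!r} positions not monotone in time")

    def position(self, t: float) -> float:
        ts = np.array(sorted(self.positions), float)
        ls = np.array([self.positions[x] for x in ts], float)
        return float(np.interp(t, ts, ls))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthesized magnitude images.

    model 'none' is bit-reproducible regardless of seed; 'gaussian' adds
    zero-mean noise (clipped at 0, adequate at high SNR); 'rician' applies
    the magnitude of a complex-Gaussian perturbation (correct at low SNR).
    """

    model: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _interp_anchors(anchors: dict[float, float], t: float) -> float:
    ts = np.array(sorted(anchors), float)
    vs = np.array([anchors[x] for x in ts], float)
    return float(np.interp(t, ts, vs))


@dataclass
class ComponentRule:
    """Declarative description of one component field.

    The component exists inside ``layer`` (static L interval), optionally
    clipped to a time-dependent zone [zone_lo, zone_hi) whose bounds may
    reference a named front, and optionally restricted to a time window.
    T2 and amplitude are piecewise-linear in time between anchors (held
    constant outside the anchored span).  ``t2_ramp`` adds a linear-in-L
    T2 increment inside a spatial window and time range (used for the
    transient zone near the contact plane).
    """

    label: str
    layer: tuple[float, float]
    t2_anchors: dict[float, float]
    a_anchors: dict[float, float]
    zone_lo: str | float | None = None  # front name or constant L; None = layer lo
    zone_hi: str | float | None = None
    t_range: tuple[float, float] = (0.0, math.inf)
    # (L_start, L_end, delta_t2_at_end, t_start, t_end)
    t2_ramp: tuple[float, float, float, float, float] | None = None

    def _bound(self, b, t: float, fronts: dict[str, FrontTruth], default: float) -> float:
        if b is None:
            return default
        if isinstance(b, str):
            return fronts[b].position(t)
        return float(b)

    def present(self, L: float, t: float, fronts: dict[str, FrontTruth]) -> bool:
        if not (self.t_range[0] <= t < self.t_range[1]):
            return False
        lo = max(self.layer[0], self._bound(self.zone_lo, t, fronts, self.layer[0]))
        hi = min(self.layer[1], self._bound(self.zone_hi, t, fronts, self.layer[1]))
        return lo <= L < hi

    def component(self, L: float, t: float) -> ExpComponent:
        t2 = _interp_anchors(self.t2_anchors, t)
        amp = _interp_anchors(self.a_anchors, t)
        if self.t2_ramp is not None:
            ls, le, delta, t0, t1 = self.t2_ramp
            if t0 <= t < t1 and L > ls:
                t2 += delta * min(1.0, (L - ls) / (le - ls))
        return ExpComponent(amplitude=amp, t2_ms=t2, label=self.label)


@dataclass
class PhantomScenario:
    """Ground-truth spatiotemporal component field of a layered stack."""

    name: str
    layers: dict[str, tuple[float, float]]
    rules: list[ComponentRule]
    fronts: list[FrontTruth]
    baseline_offset: float = 0.0
    time_span: tuple[float, float] = (0.0, 2880.0)
    time_points: tuple[float, ...] = (15, 30, 45, 60, 75, 90, 105, 120)
    origin_row: int = 64  # image row whose top edge sits at L = 0
    stack_cols: tuple[int, int] = (64, 192)  # columns occupied by the stack

    def __post_init__(self) -> None:
        self._validate_layers()
        fronts = self.front_map
        for fr in self.fronts:
            lo = min(b[0] for b in self.layers.values())
            hi = max(b[1] for b in self.layers.values())
            for pos in fr.positions.values():
                if not (lo <= pos <= hi):
                    raise ValueError(
                        f"front {fr.name!r} position {pos} outside geometry [{lo}, {hi}]"
                    )
        for rule in self.rules:
            if rule.label not in COMPONENT_LABELS:
                raise ValueError(f"unknown component label {rule.label!r}")
            for ref in (rule.zone_lo, rule.zone_hi):
                if isinstance(ref, str) and ref not in fronts:
                    raise ValueError(f"rule references unknown front {ref!r}")

    def _validate_layers(self) -> None:
        named = [(n, b) for n, b in self.layers.items()]
        for i, (ni, bi) in enumerate(named):
            if bi[0] >= bi[1]:
                raise ValueError(f"layer {ni!r} interval empty")
            for nj, bj in named[i + 1:]:
                if bi[0] < bj[1] and bj[0] < bi[1]:
                    raise ValueError(f"layers {ni!r} and {nj!r} overlap")
        if "dressing" in self.layers and "substrate" in self.layers:
            if self.layers["dressing"][1] != self.layers["substrate"][0]:
                raise ValueError("dressing and substrate must be contiguous")

    @property
    def front_map(self) -> dict[str, FrontTruth]:
        return {f.name: f for f in self.fronts}

    @property
    def contact_plane_mm(self) -> float:
        return self.layers["dressing"][1]

    def layer_of(self, L: float) -> str | None:
        for name, (lo, hi) in self.layers.items():
            if lo <= L < hi or (L == hi and name == "substrate"):
                return name
        return None

    def components_at(self, L: float, t: float) -> list[ExpComponent]:
        return truth_components(self, L, t)

    def component_count_at(self, L: float, t: float) -> int:
        return len(truth_components(self, L, t, strict=False))

    def anchor_table(self) -> pd.DataFrame:
        """Materialize the sparse anchor table as a tidy DataFrame."""
        rows = []
        for rule in self.rules:
            for t in sorted(set(rule.t2_anchors) | set(rule.a_anchors)):
                rows.append(
                    {
                        "t_min": t,
                        "layer_lo_mm": rule.layer[0],
                        "layer_hi_mm": rule.layer[1],
                        "label": rule.label,
                        "A": _interp_anchors(rule.a_anchors, t),
                        "T2_ms": _interp_anchors(rule.t2_anchors, t),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "layers": {k: list(v) for k, v in self.layers.items()},
            "baseline_offset": self.baseline_offset,
            "time_span": list(self.time_span),
            "time_points": list(self.time_points),
            "origin_row": self.origin_row,
            "stack_cols": list(self.stack_cols),
            "fronts": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "layer": f.layer,
                    "direction": f.direction,
                    "positions": {float(k): float(v) for k, v in f.positions.items()},
                }
                for f in self.fronts
            ],
            "rules": [
                {
                    "label": r.label,
                    "layer": list(r.layer),
                    "t2_anchors": {float(k): float(v) for k, v in r.t2_anchors.items()},
                    "a_anchors": {float(k): float(v) for k, v in r.a_anchors.items()},
                    "zone_lo": r.zone_lo,
                    "zone_hi": r.zone_hi,
                    "t_range": [r.t_range[0], None if math.isinf(r.t_range[1]) else r.t_range[1]],
                    "t2_ramp": list(r.t2_ramp) if r.t2_ramp else None,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomScenario":
        fronts = [
            FrontTruth(
                name=f["name"],
                kind=f["kind"],
                positions={float(k): float(v) for k, v in f["positions"].items()},
                layer=f.get("layer", "dressing"),
                direction=f.get("direction", "toward_dressing_top"),
            )
            for f in d.get("fronts", [])
        ]
        rules = []
        for r in d["rules"]:
            tr = r.get("t_range", [0.0, None])
            rules.append(
                ComponentRule(
                    label=r["label"],
                    layer=tuple(r["layer"]),
                    t2_anchors={float(k): float(v) for k, v in r["t2_anchors"].items()},
                    a_anchors={float(k): float(v) for k, v in r["a_anchors"].items()},
                    zone_lo=r.get("zone_lo"),
                    zone_hi=r.get("zone_hi"),
                    t_range=(float(tr[0]), math.inf if tr[1] is None else float(tr[1])),
                    t2_ramp=tuple(r["t2_ramp"]) if r.get("t2_ramp") else None,
                )
            )
        return cls(
            name=d.get("name", "custom"),
            layers={k: tuple(v) for k, v in d["layers"].items()},
            rules=rules,
            fronts=fronts,
            baseline_offset=float(d.get("baseline_offset", 0.0)),
            time_span=tuple(d.get("time_span", (0.0, 2880.0))),
            time_points=tuple(d.get("time_points", (15, 30, 45, 60, 75, 90, 105, 120))),
            origin_row=int(d.get("origin_row", 64)),
            stack_cols=tuple(d.get("stack_cols", (64, 192))),
        )


def truth_components(
    scenario: PhantomScenario, L: float, t: float, strict: bool = True
) -> list[ExpComponent]:
    """Ground-truth components at position L (mm) and time t (min).

    Values are piecewise-linear interpolations of the scenario's sparse
    anchors; the component count changes exactly at front positions.
    Components are returned sorted by ascending T2.  With ``strict`` the
    query must lie inside the geometry and time span; otherwise positions
    outside any layer return an empty list (void).
    """
    if strict:
        if not (scenario.time_span[0] <= t <= scenario.time_span[1]):
            raise ValueError(f"time {t} outside scenario span {scenario.time_span}")
        if scenario.layer_of(L) is None:
            raise ValueError(f"position L={L} mm outside scenario geometry")
    fronts = scenario.front_map
    comps = [
        rule.component(L, t)
        for rule in scenario.rules
        if rule.present(L, t, fronts)
    ]
    return sorted(comps, key=lambda c: c.t2_ms)


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

_LAYERS = {"reference": (-3.0, -1.0), "dressing": (0.0, 6.0), "substrate": (6.0, 12.0)}
_REFERENCE_RULE = ComponentRule(
    label="reference",
    layer=(-3.0, -1.0),
    t2_anchors={0.0: 800.0},
    a_anchors={0.0: 250.0},
)
_FBS_TIMES = (15, 30, 45, 60, 75, 90, 105, 120)
_PG_TIMES = (15, 30, 45, 60, 75, 90, 105, 120, 1440, 2880)


def _fbs_scenario(name, water_t2, water_a, pg_t2, pg_a, sub_t2, sub_a) -> PhantomScenario:
    fronts = [
        # PG survives only above (L <) this front; depleted zone grows upward
        # from the contact until the PG pool vanishes entirely by 30 min.
        FrontTruth(
            name="pg_depletion",
            kind="component_disappearance",
            positions={0.0: 6.0, 15.0: 1.5, 30.0: 0.0},
            layer="dressing",
            direction="toward_dressing_top",
        ),
        # Transient zone of elevated water T2 toward the contact plane.
        FrontTruth(
            name="transient_zone",
            kind="trend_change",
            positions={15.0: 5.7, 45.0: 5.7},
            layer="dressing",
            direction="toward_dressing_top",
        ),
    ]
    rules = [
        ComponentRule(
            label="water_dressing",
            layer=(0.0, 6.0),
            t2_anchors=water_t2,
            a_anchors=water_a,
            t2_ramp=(5.7, 6.0, 45.0, 1.0, 60.0),
        ),
        ComponentRule(
            label="pg_dressing",
            layer=(0.0, 6.0),
            t2_anchors=pg_t2,
            a_anchors=pg_a,
            zone_hi="pg_depletion",
        ),
        ComponentRule(
            label="water_substrate",
            layer=(6.0, 12.0),
            t2_anchors=sub_t2,
            a_anchors=sub_a,
        ),
        _REFERENCE_RULE,
    ]
    return PhantomScenario(
        name=name,
        layers=dict(_LAYERS),
        rules=rules,
        fronts=fronts,
        time_span=(0.0, 120.0),
        time_points=_FBS_TIMES,
    )


def _m8_fbs() -> PhantomScenario:
    return _fbs_scenario(
        "M8_FBS",
        water_t2={0.0: 48.9, 15.0: 53.0, 60.0: 75.0, 120.0: 87.0},
        water_a={0.0: 195.0, 15.0: 197.0, 120.0: 205.0},
        pg_t2={0.0: 394.0},
        pg_a={0.0: 8.0},
        sub_t2={15.0: 133.0, 120.0: 103.0},
        sub_a={15.0: 180.0, 120.0: 187.0},
    )


def _m8l_fbs() -> PhantomScenario:
    return _fbs_scenario(
        "M8L_FBS",
        water_t2={0.0: 29.7, 15.0: 38.0, 60.0: 90.0, 120.0: 95.0},
        water_a={0.0: 199.0, 15.0: 200.0, 120.0: 208.0},
        pg_t2={0.0: 296.0},
        pg_a={0.0: 14.2},
        sub_t2={15.0: 134.0, 120.0: 109.0},
        sub_a={15.0: 180.0, 120.0: 187.0},
    )


def _m8_pg() -> PhantomScenario:
    fronts = [
        FrontTruth(
            name="dressing_front",
            kind="component_appearance",
            positions={0.0: 6.0, 15.0: 4.0, 60.0: 3.5, 120.0: 3.0, 1440.0: 0.0},
            layer="dressing",
            direction="toward_dressing_top",
        ),
        FrontTruth(
            name="substrate_front",
            kind="component_appearance",
            positions={0.0: 6.0, 15.0: 7.4, 60.0: 8.4, 120.0: 9.3, 1440.0: 12.0},
            layer="substrate",
            direction="into_substrate",
        ),
    ]
    dressing = (0.0, 6.0)
    substrate = (6.0, 12.0)
    rules = [
        # --- dressing, above the front: original two-component pool ---
        ComponentRule("water_dressing", dressing, {0.0: 48.9}, {0.0: 195.0},
                      zone_hi="dressing_front"),
        ComponentRule("pg_dressing", dressing, {0.0: 394.0}, {0.0: 8.0},
                      zone_hi="dressing_front"),
        # --- dressing, PG-invaded zone: bound water / intermediate / rich PG ---
        ComponentRule("water_dressing", dressing,
                      {15.0: 15.0, 120.0: 15.0, 1440.0: 14.0, 2880.0: 13.0},
                      {15.0: 120.0, 2880.0: 100.0}, zone_lo="dressing_front"),
        ComponentRule("intermediate", dressing, {15.0: 50.0},
                      {15.0: 40.0, 1440.0: 70.0}, zone_lo="dressing_front"),
        ComponentRule("pg_dressing", dressing,
                      {15.0: 420.0, 120.0: 430.0, 1440.0: 300.0, 2880.0: 250.0},
                      {15.0: 30.0, 1440.0: 60.0}, zone_lo="dressing_front"),
        # --- substrate beyond the front: native PG-in-sponge pair ---
        ComponentRule("pg_short_substrate", substrate, {0.0: 100.0}, {0.0: 160.0},
                      zone_lo="substrate_front"),
        ComponentRule("pg_long_substrate", substrate, {0.0: 400.0}, {0.0: 40.0},
                      zone_lo="substrate_front"),
        # --- substrate mixing zone near the contact: split + intermediate ---
        ComponentRule("intermediate", substrate,
                      {15.0: 45.0, 1440.0: 20.0, 2880.0: 13.0},
                      {15.0: 50.0}, zone_hi="substrate_front"),
        ComponentRule("pg_short_substrate", substrate,
                      {15.0: 140.0, 1440.0: 60.0, 2880.0: 50.0},
                      {15.0: 140.0}, zone_hi="substrate_front"),
        ComponentRule("pg_long_substrate", substrate,
                      {15.0: 450.0, 1440.0: 300.0, 2880.0: 250.0},
                      {15.0: 45.0}, zone_hi="substrate_front"),
        _REFERENCE_RULE,
    ]
    return PhantomScenario(
        name="M8_PG",
        layers=dict(_LAYERS),
        rules=rules,
        fronts=fronts,
        time_span=(0.0, 2880.0),
        time_points=_PG_TIMES,
    )


def _m8l_pg() -> PhantomScenario:
    fronts = [
        FrontTruth(
            name="dressing_front",
            kind="component_appearance",
            positions={0.0: 6.0, 15.0: 5.5, 60.0: 5.0, 120.0: 4.5, 1440.0: 0.0},
            layer="dressing",
            direction="toward_dressing_top",
        ),
        # Upper edge of the three-component band: at 24 h the band has
        # shrunk to L in [0, 2); by 48 h it is gone.
        FrontTruth(
            name="dressing_zone_end",
            kind="component_disappearance",
            positions={120.0: 6.0, 1440.0: 2.0, 2880.0: 0.0},
            layer="dressing",
            direction="toward_dressing_top",
        ),
        FrontTruth(
            name="substrate_front",
            kind="component_appearance",
            positions={0.0: 6.0, 15.0: 7.4, 60.0: 8.4, 120.0: 9.3},
            layer="substrate",
            direction="into_substrate",
        ),
    ]
    dressing = (0.0, 6.0)
    substrate = (6.0, 12.0)
    water_t2 = {0.0: 29.7, 1440.0: 40.0, 2880.0: 60.0}
    water_a = {0.0: 199.0, 2880.0: 180.0}
    pg_t2 = {0.0: 296.0, 1440.0: 290.0, 2880.0: 300.0}
    pg_a = {0.0: 14.2, 2880.0: 30.0}
    rules = [
        # outside the band, on the top side (L < dressing_front)
        ComponentRule("water_dressing", dressing, water_t2, water_a,
                      zone_hi="dressing_front"),
        ComponentRule("pg_dressing", dressing, pg_t2, pg_a, zone_hi="dressing_front"),
        # outside the band, on the contact side (L >= dressing_zone_end)
        ComponentRule("water_dressing", dressing, water_t2, water_a,
                      zone_lo="dressing_zone_end"),
        ComponentRule("pg_dressing", dressing, pg_t2, pg_a, zone_lo="dressing_zone_end"),
        # inside the three-component band
        ComponentRule("water_dressing", dressing, {15.0: 12.0}, {15.0: 120.0},
                      zone_lo="dressing_front", zone_hi="dressing_zone_end"),
        ComponentRule("intermediate", dressing, {15.0: 50.0}, {15.0: 40.0},
                      zone_lo="dressing_front", zone_hi="dressing_zone_end"),
        ComponentRule("pg_dressing", dressing, {15.0: 320.0}, {15.0: 30.0},
                      zone_lo="dressing_front", zone_hi="dressing_zone_end"),
        # substrate: native pair beyond the front (mixing zone ends by 24 h)
        ComponentRule("pg_short_substrate", substrate, {0.0: 100.0}, {0.0: 160.0},
                      zone_lo="substrate_front", t_range=(0.0, 1440.0)),
        ComponentRule("pg_long_substrate", substrate, {0.0: 400.0}, {0.0: 40.0},
                      zone_lo="substrate_front", t_range=(0.0, 1440.0)),
        ComponentRule("intermediate", substrate, {15.0: 45.0}, {15.0: 50.0},
                      zone_hi="substrate_front", t_range=(0.0, 1440.0)),
        ComponentRule("pg_short_substrate", substrate, {15.0: 140.0}, {15.0: 140.0},
                      zone_hi="substrate_front", t_range=(0.0, 1440.0)),
        ComponentRule("pg_long_substrate", substrate, {15.0: 450.0}, {15.0: 45.0},
                      zone_hi="substrate_front", t_range=(0.0, 1440.0)),
        # substrate after the mixing zone has dissolved (PG hydration at 48 h)
        ComponentRule("pg_short_substrate", substrate,
                      {1440.0: 110.0, 2880.0: 120.0}, {1440.0: 160.0},
                      t_range=(1440.0, math.inf)),
        ComponentRule("pg_long_substrate", substrate,
                      {1440.0: 420.0, 2880.0: 600.0}, {1440.0: 40.0},
                      t_range=(1440.0, math.inf)),
        _REFERENCE_RULE,
    ]
    return PhantomScenario(
        name="M8L_PG",
        layers=dict(_LAYERS),
        rules=rules,
        fronts=fronts,
        time_span=(0.0, 2880.0),
        time_points=_PG_TIMES,
    )


_BUILDERS = {
    "M8_FBS": _m8_fbs,
    "M8L_FBS": _m8l_fbs,
    "M8_PG": _m8_pg,
    "M8L_PG": _m8l_pg,
}

_OVERRIDABLE = (
    "time_points",
    "time_span",
    "baseline_offset",
    "origin_row",
    "stack_cols",
    "layers",
)


def build_scenario(name: str, overrides: dict | None = None) -> PhantomScenario:
    """Construct a canned scenario (or 'custom' from a full description).

    ``overrides`` may replace scalar scenario fields (time_points,
    baseline_offset, origin_row, stack_cols, layers, time_span); for
    name='custom' it must be a full scenario dictionary (see
    :meth:`PhantomScenario.from_dict`).  Construction is deterministic.
    """
    overrides = dict(overrides or {})
    if name == "custom":
        if not overrides:
            raise ValueError("custom scenario requires a full description")
        return PhantomScenario.from_dict({"name": "custom", **overrides})
    if name not in _BUILDERS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    scenario = _BUILDERS[name]()
    for key, value in overrides.items():
        if key not in _OVERRIDABLE:
            raise ValueError(f"cannot override field {key!r}")
        if key in ("time_points", "time_span", "stack_cols"):
            value = tuple(value)
        scenario = replace(scenario, **{key: value})
    return scenario


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def decay_signal(
    components: list[ExpComponent], times_ms: np.ndarray, y0: float = 0.0
) -> np.ndarray:
    """Multi-exponential echo-train signal y0 + sum_i A_i exp(-t/T2_i)."""
    sig = np.full(len(times_ms), float(y0))
    for c in components:
        sig += c.amplitude * np.exp(-times_ms / c.t2_ms)
    return sig


def synthesize_stack(
    scenario: PhantomScenario,
    grid: AcquisitionGrid | None = None,
    t: float = 15.0,
    noise: NoiseSpec = NoiseSpec(),
):
    """Synthesize one multi-echo image stack at acquisition time t (min).

    Every pixel's echo-train intensity follows the multi-exponential decay
    of its ground-truth components; reference-compartment pixels carry a
    single long-T2 water component of time-constant amplitude; void pixels
    carry the baseline offset only.  Gaussian/Rician noise is seeded and
    reproducible; the noiseless stack is bit-reproducible.
    """
    from .stack_io import MultiEchoStack

    grid = grid or AcquisitionGrid()
    n_rows, n_cols = grid.matrix
    pix = grid.pixel_mm[0]
    times = grid.echo_times_ms
    data = np.full((grid.n_echoes, n_rows, n_cols), scenario.baseline_offset, dtype=np.float64)
    c0, c1 = scenario.stack_cols
    for i in range(n_rows):
        L = (i - scenario.origin_row + 0.5) * pix
        comps = truth_components(scenario, L, t, strict=False)
        if not comps:
            continue
        data[:, i, c0:c1] = decay_signal(comps, times, scenario.baseline_offset)[:, None]
    if noise.model == "gaussian" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data = np.clip(data + rng.normal(0.0, noise.sigma, data.shape), 0.0, None)
    elif noise.model == "rician" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        re = data + rng.normal(0.0, noise.sigma, data.shape)
        im = rng.normal(0.0, noise.sigma, data.shape)
        data = np.hypot(re, im)
    return MultiEchoStack(data=data.astype(np.float32), grid=grid, time_point_min=t)


# ---------------------------------------------------------------------------
# Ground-truth export
# ---------------------------------------------------------------------------

def export_truth(
    scenario: PhantomScenario,
    times: list[float] | None = None,
    positions_mm: np.ndarray | None = None,
    path=None,
) -> pd.DataFrame:
    """Tabulate ground-truth components (t_min, L_mm, label, A, T2_ms)."""
    grid = AcquisitionGrid()
    if times is None:
        times = list(scenario.time_points)
    if positions_mm is None:
        pix = grid.pixel_mm[0]
        n = grid.matrix[0]
        positions_mm = (np.arange(n) - scenario.origin_row + 0.5) * pix
    rows = []
    for t in times:
        for L in positions_mm:
            for c in truth_components(scenario, float(L), float(t), strict=False):
                rows.append(
                    {"t_min": t, "L_mm": L, "component_label": c.label,
                     "A": c.amplitude, "T2_ms": c.t2_ms}
                )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.10g")
    return df


def export_fronts(scenario: PhantomScenario, path=None) -> pd.DataFrame:
    """Tabulate ground-truth front trajectories (kind, t_min, L_mm)."""
    rows = []
    for f in scenario.fronts:
        for t in sorted(f.positions):
            rows.append(
                {"name": f.name, "kind": f.kind, "layer": f.layer,
                 "direction": f.direction, "t_min": t, "L_mm": f.positions[t]}
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.10g")
    return df


def scenario_to_yaml(scenario: PhantomScenario, path=None) -> str:
    text = yaml.safe_dump(scenario.to_dict(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def scenario_from_yaml(source) -> PhantomScenario:
    """Load a scenario from a YAML string, file object, or path."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    elif isinstance(source, str) and "\n" in source:
        data = yaml.safe_load(io.StringIO(source))
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    return PhantomScenario.from_dict(data)
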