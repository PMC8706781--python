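"""Multi-exponential decay fitting and 1D parametric profiling.

Each pixel's echo-train intensity is modeled as

    f(t) = y0 + sum_{i=1..n} A_i * exp(-t / T2_i),      n = 1, 2 or 3

with nonnegative amplitudes and positive relaxation times.  The fit is a
bounded nonlinear least squares (Levenberg-Marquardt-type trust-region
solver with an analytic Jacobian), initialized by log-linear tail fitting
with residual peeling and guarded by randomized restarts.  Model order is
chosen stepwise by an F-test on nested residual sums of squares combined
with an amplitude floor of k*sigma_noise, so that components below the
detection limit are never reported.  Applying the fitter along the stack
axis L yields 1D parametric profiles of T2 and amplitude per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phantom_sim import ExpComponent

if TYPE_CHECKING:  # pragma: no cover
    from .stack_io import ProfileStack

__all__ = [
    "DecayCurve",
    "FitConfig",
    "MultiExpFit",
    "ParametricProfileSeries",
    "fit_decay",
    "select_model",
    "fit_profile_series",
    "label_components",
]


@dataclass
class DecayCurve:
    """One pixel's (or ROI's) signal intensity versus echo time."""

    times_ms: np.ndarray
    intensities: np.ndarray
    origin: tuple = ("", 0.0)  # (L_mm or ROI id, time_point_min)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times_ms.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class FitConfig:
    """Tunable fitting/selection parameters.

    f_level: significance of the nested F-test for accepting an extra
    component.  amp_floor_k: an added component must exceed k*sigma_noise.
    merge_rel_tol: two fitted T2s closer than this relative spacing are
    merged (amplitudes summed) before reporting.  noise_sigma: known noise
    level; if None it is estimated from late-echo residuals.
    """

    f_level: float = 0.05
    amp_floor_k: float = 3.0
    merge_rel_tol: float = 0.05
    max_restarts: int = 5
    noise_sigma: float | None = None
    noise_tail_echoes: int = 32
    void_threshold: float | None = None
    seed: int = 0
    xtol: float = 1e-12
    ftol: float = 1e-12


@dataclass
class MultiExpFit:
    """Fitted multi-exponential model with diagnostics.

    components are sorted by ascending T2; r2 is the coefficient of
    determination; param_std holds per-parameter standard errors from the
    Jacobian-based covariance (ordered y0, A_1..A_n, T2_1..T2_n).
    """

    y0: float
    components: list[ExpComponent]
    r2: float
    rss: float
    residual_norm: float
    param_std: np.ndarray | None = None
    flags: tuple[str, ...] = ()
    origin: tuple = ("", 0.0)

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def converged(self) -> bool:
        return "nonconverged" not in self.flags

    def model(self, times_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(times_ms, float)
        out = np.full(t.shape, self.y0)
        for c in self.components:
            out += c.amplitude * np.exp(-t / c.t2_ms)
        return out

    @property
    def intercept(self) -> float:
        """Back-extrapolated signal at t=0: y0 + sum(A_i)."""
        return self.y0 + sum(c.amplitude for c in self.components)


def _model(params: np.ndarray, t: np.ndarray, n: int) -> np.ndarray:
    y0 = params[0]
    amps = params[1:1 + n]
    t2s = params[1 + n:1 + 2 * n]
    return y0 + np.exp(-t[:, None] / t2s[None, :]) @ amps


def _jac(params: np.ndarray, t: np.ndarray, n: int, y: np.ndarray) -> np.ndarray:
    amps = params[1:1 + n]
    t2s = params[1 + n:1 + 2 * n]
    E = np.exp(-t[:, None] / t2s[None, :])
    J = np.empty((len(t), 1 + 2 * n))
    J[:, 0] = 1.0
    J[:, 1:1 + n] = E
    J[:, 1 + n:] = amps[None, :] * E * t[:, None] / t2s[None, :] ** 2
    return J


def _default_bounds(t: np.ndarray, y: np.ndarray, n: int):
    ymax = max(float(np.max(y)), 1e-12)
    lo = np.concatenate([[0.0], np.zeros(n), np.full(n, t[0] / 2)])
    hi = np.concatenate([[ymax], np.full(n, 10 * ymax), np.full(n, 10 * t[-1])])
    return lo, hi


def _peel_init(t: np.ndarray, y: np.ndarray, n: int, lo, hi) -> np.ndarray:
    """Log-linear tail fit for the slowest component, then peel residuals."""
    ymax = float(np.max(y))
    y0g = max(0.0, 0.9 * float(np.min(y)))
    resid = y - y0g
    amps, t2s = [], []
    ok = True
    for _ in range(n):
        idx = np.flatnonzero(resid > max(1e-12, 1e-4 * ymax))
        if len(idx) < 4:
            ok = False
            break
        tail = idx[int(len(idx) * 0.6):]
        if len(tail) < 3:
            tail = idx[-3:]
        slope, intercept = np.polyfit(t[tail], np.log(resid[tail]), 1)
        if slope >= 0:
            t2 = 10 * t[-1]
        else:
            t2 = -1.0 / slope
        amp = math.exp(intercept)
        t2s.append(t2)
        amps.append(amp)
        resid = resid - amp * np.exp(-t / t2)
    if not ok or len(amps) < n:
        # geometric spread fallback
        t2s = list(np.geomspace(3 * t[0], t[-1] / 3, n)[::-1])
        amps = [max(ymax - y0g, 1e-6) / n] * n
    order = np.argsort(t2s)  # ascending T2 in parameter vector
    params = np.concatenate(
        [[y0g], np.array(amps)[order], np.array(t2s)[order]]
    )
    return np.clip(params, lo + 1e-12, hi - 1e-12)


def _sorted_components(params: np.ndarray, n: int) -> tuple[float, list[ExpComponent]]:
    y0 = float(params[0])
    amps = params[1:1 + n]
    t2s = params[1 + n:1 + 2 * n]
    order = np.argsort(t2s)
    comps = [
        ExpComponent(amplitude=float(max(amps[i], 0.0)), t2_ms=float(t2s[i]))
        for i in order
    ]
    return y0, comps


def _merge_close(comps: list[ExpComponent], rel_tol: float) -> tuple[list[ExpComponent], bool]:
    """Merge components whose T2s are closer than rel_tol (amplitudes summed)."""
    merged = False
    comps = sorted(comps, key=lambda c: c.t2_ms)
    out: list[ExpComponent] = []
    for c in comps:
        if out and (c.t2_ms - out[-1].t2_ms) < rel_tol * c.t2_ms:
            prev = out.pop()
            tot = prev.amplitude + c.amplitude
            t2 = (
                (prev.amplitude * prev.t2_ms + c.amplitude * c.t2_ms) / tot
                if tot > 0
                else 0.5 * (prev.t2_ms + c.t2_ms)
            )
            out.append(ExpComponent(amplitude=tot, t2_ms=t2))
            merged = True
        else:
            out.append(c)
    return out, merged


def fit_decay(
    curve: DecayCurve,
    n: int,
    init: Sequence[float] | None = None,
    bounds: tuple | None = None,
    config: FitConfig | None = None,
) -> MultiExpFit:
    """Fit an n-component (1-3) multi-exponential model to one decay curve.

    Nonlinear least squares with nonnegativity on amplitudes and
    positivity on T2s; the initial point comes from log-linear residual
    peeling (or a caller-supplied warm start) with up to
    ``config.max_restarts`` randomized restarts on poor convergence.
    Components whose T2s collapse within ``merge_rel_tol`` are merged.
    Non-convergence is flagged, never silently zeroed.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    config = config or FitConfig()
    t = curve.times_ms
    y = curve.intensities
    if len(t) < 2 * n + 1:
        raise ValueError(f"need at least {2 * n + 1} points for n={n}")
    if np.ptp(y) == 0:
        comp = ExpComponent(amplitude=0.0, t2_ms=float(t[len(t) // 2]))
        return MultiExpFit(
            y0=float(y[0]), components=[comp],
            r2=0.0, rss=0.0, residual_norm=0.0,
            flags=("degenerate",), origin=curve.origin,
        )
    lo, hi = _default_bounds(t, y, n) if bounds is None else bounds
    p0 = (
        np.clip(np.asarray(init, float), lo + 1e-12, hi - 1e-12)
        if init is not None
        else _peel_init(t, y, n, lo, hi)
    )

    def run(p_start):
        return optimize.least_squares(
            lambda p: _model(p, t, n) - y,
            p_start,
            jac=lambda p: _jac(p, t, n, y),
            bounds=(lo, hi),
            method="trf",
            xtol=config.xtol,
            ftol=config.ftol,
            gtol=1e-12,
            max_nfev=400,
        )

    best = run(p0)
    tss = float(np.sum((y - y.mean()) ** 2))
    rng = np.random.default_rng(config.seed)
    # Restart only when the residual clearly exceeds the noise floor; the
    # floor comes from config or a first-difference estimate on the tail,
    # so noiseless fits are pushed to machine precision while noisy fits
    # stop at the statistically expected RSS.
    if config.noise_sigma is not None:
        sigma0 = config.noise_sigma
    else:
        tail = y[-min(64, len(y) // 2):]
        sigma0 = float(np.std(np.diff(tail)) / math.sqrt(2)) if len(tail) > 2 else 0.0
    target = max(1e-12 * tss, 2.0 * len(t) * sigma0 ** 2)
    tries = 0
    while 2 * best.cost > target and tries < config.max_restarts:
        jitter = rng.lognormal(0.0, 0.4, size=p0.shape)
        res = run(np.clip(p0 * jitter, lo + 1e-12, hi - 1e-12))
        if res.cost < best.cost:
            best = res
        tries += 1

    y0, comps = _sorted_components(best.x, n)
    comps, merged = _merge_close(comps, config.merge_rel_tol)
    if merged:
        model = np.full(t.shape, y0)
        for c in comps:
            model += c.amplitude * np.exp(-t / c.t2_ms)
        rss = float(np.sum((model - y) ** 2))
    else:
        rss = float(2 * best.cost)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    flags = []
    if not best.success:
        flags.append("nonconverged")
    if merged:
        flags.append("merged")
    param_std = None
    try:
        J = _jac(best.x, t, n, y)
        dof = max(len(t) - len(best.x), 1)
        cov = rss / dof * np.linalg.pinv(J.T @ J)
        param_std = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        flags.append("singular_covariance")
    return MultiExpFit(
        y0=y0,
        components=comps,
        r2=r2,
        rss=rss,
        residual_norm=math.sqrt(rss),
        param_std=param_std,
        flags=tuple(flags),
        origin=curve.origin,
    )


def _estimate_sigma(curve: DecayCurve, fit: MultiExpFit, n_tail: int) -> float:
    resid = curve.intensities - fit.model(curve.times_ms)
    tail = resid[-n_tail:] if len(resid) > n_tail else resid
    return float(np.std(tail))


def select_model(
    curve: DecayCurve,
    max_n: int = 3,
    config: FitConfig | None = None,
    init: Sequence[float] | None = None,
) -> MultiExpFit:
    """Choose the number of components (1..max_n) for one decay curve.

    Fits model orders stepwise; a larger model is accepted only if (a) a
    nested F-test on residual sums of squares favors it at
    ``config.f_level`` and (b) every component of the larger model exceeds
    the amplitude floor k*sigma_noise (sigma from late-echo residuals or
    ``config.noise_sigma``).  A warm start ``init`` (for its matching
    order) speeds up profile sweeps.
    """
    config = config or FitConfig()
    t = curve.times_ms
    y = curve.intensities
    ymax = float(np.max(np.abs(y))) if len(y) else 0.0
    fits: dict[int, MultiExpFit] = {}

    def get_fit(k: int) -> MultiExpFit:
        if k not in fits:
            use_init = init if init is not None and len(init) == 1 + 2 * k else None
            fits[k] = fit_decay(curve, k, init=use_init, config=config)
        return fits[k]

    current = get_fit(1)
    if "degenerate" in current.flags:
        return current
    n_pts = len(t)
    for k in range(2, max_n + 1):
        # a numerically perfect smaller model cannot be improved upon
        if current.rss <= n_pts * (1e-7 * ymax) ** 2:
            break
        candidate = get_fit(k)
        p_small = 1 + 2 * current.n
        p_big = 1 + 2 * k
        dof_big = n_pts - p_big
        if dof_big <= 0 or candidate.rss >= current.rss:
            break
        sigma = (
            config.noise_sigma
            if config.noise_sigma is not None
            else _estimate_sigma(curve, candidate, config.noise_tail_echoes)
        )
        fstat = ((current.rss - candidate.rss) / (p_big - p_small)) / (
            max(candidate.rss, 1e-300) / dof_big
        )
        p_value = stats.f.sf(fstat, p_big - p_small, dof_big)
        amp_floor = max(config.amp_floor_k * sigma, 1e-6 * ymax)
        amps_ok = (
            candidate.n == k  # did not collapse/merge
            and all(c.amplitude > amp_floor for c in candidate.components)
        )
        if p_value < config.f_level and amps_ok:
            current = candidate
        else:
            break
    if not current.converged and all(not f.converged for f in fits.values()):
        current = replace(current, flags=current.flags + ("all_orders_nonconverged",))
    return current


# ---------------------------------------------------------------------------
# Parametric profile series
# ---------------------------------------------------------------------------

class ParametricProfileSeries:
    """Per-(time point, position) fitted parameters along the stack axis.

    ``table`` is tidy: one row per fitted component (void positions get a
    single row with n=0 and NaN parameters), with columns
    t_min, L_mm, n, comp_idx, label, A, T2_ms, y0, r2, flags.
    """

    COLUMNS = ["t_min", "L_mm", "n", "comp_idx", "label", "A", "T2_ms", "y0", "r2", "flags"]

    def __init__(self, table: pd.DataFrame, layers: dict[str, tuple[float, float]] | None = None):
        self.table = table.reset_index(drop=True)
        self.layers = dict(layers or {})

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.table["t_min"].unique())

    @property
    def positions_mm(self) -> np.ndarray:
        return np.sort(self.table["L_mm"].unique())

    def _layer_mask(self, L: pd.Series, layer: str | None):
        if layer is None:
            return np.ones(len(L), bool)
        lo, hi = self.layers[layer]
        return (L >= lo) & (L < hi)

    def component_count(self, t: float, layer: str | None = None):
        """(positions, counts) of fitted components at time t, within a layer."""
        df = self.table[np.isclose(self.table["t_min"], t)]
        df = df[self._layer_mask(df["L_mm"], layer)]
        per_pos = df.groupby("L_mm")["n"].first().sort_index()
        return per_pos.index.to_numpy(), per_pos.to_numpy().astype(int)

    def parameter_profile(
        self, t: float, label: str, parameter: str = "T2_ms", layer: str | None = None
    ):
        """(positions, values) of one labeled component's parameter vs L."""
        df = self.table[
            np.isclose(self.table["t_min"], t) & (self.table["label"] == label)
        ]
        df = df[self._layer_mask(df["L_mm"], layer)]
        df = df.sort_values("L_mm")
        return df["L_mm"].to_numpy(), df[parameter].to_numpy()

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for name, (lo, hi) in self.layers.items():
                fh.write(f"# layer {name} {lo} {hi}\n")
            self.table.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ParametricProfileSeries":
        layers = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                parts = line[1:].split()
                if parts and parts[0] == "layer":
                    layers[parts[1]] = (float(parts[2]), float(parts[3]))
        table = pd.read_csv(path, comment="#", keep_default_na=True)
        table["flags"] = table["flags"].fillna("")
        table["label"] = table["label"].fillna("")
        return cls(table, layers)


def fit_profile_series(
    profiles: list["ProfileStack"],
    config: FitConfig | None = None,
    max_n: int = 3,
    layers: dict[str, tuple[float, float]] | None = None,
) -> ParametricProfileSeries:
    """Model-select and fit every (time point, position) of a profile series.

    Positions whose signal never rises above the void threshold (default
    5*sigma_noise, with sigma estimated from the faintest rows' late
    echoes) are marked empty rather than fitted.  Fits are warm-started
    from the previous position along L.  Flagged fits propagate into the
    series without aborting the sweep.
    """
    config = config or FitConfig()
    base = profiles[0].positions_mm
    for p in profiles[1:]:
        if len(p.positions_mm) != len(base) or not np.allclose(p.positions_mm, base):
            raise ValueError("all profiles must share the same position grid")
    rows = []
    for prof in profiles:
        times = prof.grid.echo_times_ms
        sig = prof.signal
        row_max = sig.max(axis=1)
        if config.noise_sigma is not None:
            sigma = config.noise_sigma
        else:
            # late echoes of the faintest decile of rows
            k = max(1, len(row_max) // 10)
            faint = np.argsort(row_max)[:k]
            tail = sig[faint, -config.noise_tail_echoes:]
            sigma = float(np.std(tail))
        void_thr = (
            config.void_threshold
            if config.void_threshold is not None
            else max(5 * sigma, 1e-3 * float(row_max.max()), 1e-12)
        )
        cfg = replace(config, noise_sigma=sigma if config.noise_sigma is None else config.noise_sigma)
        warm: np.ndarray | None = None
        for i, L in enumerate(prof.positions_mm):
            if row_max[i] < void_thr:
                rows.append(
                    {"t_min": prof.time_point_min, "L_mm": L, "n": 0, "comp_idx": -1,
                     "label": "void", "A": np.nan, "T2_ms": np.nan, "y0": np.nan,
                     "r2": np.nan, "flags": ""}
                )
                warm = None
                continue
            curve = DecayCurve(times, sig[i], origin=(L, prof.time_point_min))
            fit = select_model(curve, max_n=max_n, config=cfg, init=warm)
            warm = np.concatenate(
                [[fit.y0], [c.amplitude for c in fit.components],
                 [c.t2_ms for c in fit.components]]
            )
            for j, c in enumerate(fit.components):
                rows.append(
                    {"t_min": prof.time_point_min, "L_mm": L, "n": fit.n,
                     "comp_idx": j, "label": "", "A": c.amplitude, "T2_ms": c.t2_ms,
                     "y0": fit.y0, "r2": fit.r2, "flags": ";".join(fit.flags)}
                )
    table = pd.DataFrame(rows, columns=ParametricProfileSeries.COLUMNS)
    return ParametricProfileSeries(table, layers)


# label assignment by layer and ascending-T2 rank, per substrate medium
_LABEL_RULES = {
    ("dressing", 1): ["water_dressing"],
    ("dressing", 2): ["water_dressing", "pg_dressing"],
    ("dressing", 3): ["water_dressing", "intermediate", "pg_dressing"],
    ("reference", 1): ["reference"],
}
_SUBSTRATE_RULES = {
    "FBS": {
        1: ["water_substrate"],
        2: ["water_substrate", "intermediate"],
        3: ["water_substrate", "intermediate", "pg_long_substrate"],
    },
    "PG": {
        1: ["pg_short_substrate"],
        2: ["pg_short_substrate", "pg_long_substrate"],
        3: ["intermediate", "pg_short_substrate", "pg_long_substrate"],
    },
}


def label_components(
    series: ParametricProfileSeries,
    substrate_medium: str = "FBS",
    layers: dict[str, tuple[float, float]] | None = None,
) -> ParametricProfileSeries:
    """Assign physical labels to fitted components by layer and T2 order.

    Within the dressing the shortest-T2 component is water-like and the
    longest PG-like (a middle component is 'intermediate'); substrate
    labels depend on the wetting medium (FBS: water pool; PG: short/long
    PG-in-sponge pools plus an intermediate when three are present).
    Components in unknown layers or counts are labeled 'intermediate'.
    """
    if substrate_medium not in _SUBSTRATE_RULES:
        raise ValueError("substrate_medium must be 'FBS' or 'PG'")
    layers = layers or series.layers
    if not layers:
        raise ValueError("no layer geometry available for labeling")

    def layer_of(L: float) -> str | None:
        for name, (lo, hi) in layers.items():
            if lo <= L < hi or (L == hi and name == "substrate"):
                return name
        return None

    table = series.table.copy()
    labels = table["label"].to_list()
    for (t, L), idx in table.groupby(["t_min", "L_mm"]).groups.items():
        sub = table.loc[idx]
        n = int(sub["n"].iloc[0])
        if n == 0:
            continue
        layer = layer_of(L)
        if layer == "substrate":
            rule = _SUBSTRATE_RULES[substrate_medium].get(n)
        else:
            rule = _LABEL_RULES.get((layer, n))
        order = sub.sort_values("T2_ms").index
        for j, ix in enumerate(order):
            if rule is not None and j < len(rule):
                labels[table.index.get_loc(ix)] = rule[j]
            else:
                labels[table.index.get_loc(ix)] = "intermediate"
    table["label"] = labels
    return ParametricProfileSeries(table, layers)
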