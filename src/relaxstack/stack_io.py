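"""Multi-echo image stack I/O and reduction to averaged 1D profiles.

A multi-echo stack is a (n_echoes, rows, cols) magnitude-image array.  It
is stored on disk as a multi-page TIFF (one page per echo) with a JSON
sidecar carrying the acquisition grid and acquisition time.  For
profiling, a narrow vertical segment (default 10 pixels wide) is averaged
row-wise into a 1D profile stack: signal(position, echo), with the stack
axis L in mm assigned at pixel centers, L = 0 at the user-designated
top-of-dressing row and increasing toward/through the substrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquisition import AcquisitionGrid

__all__ = [
    "MultiEchoStack",
    "ProfileStack",
    "ReferenceReport",
    "read_stack",
    "write_stack",
    "extract_profile",
    "reference_check",
    "profile_to_csv",
    "profile_from_csv",
]


@dataclass
class MultiEchoStack:
    """One acquisition: a 2D magnitude image per echo time n*TE."""

    data: np.ndarray  # (echo, row, col), a.u.
    grid: AcquisitionGrid
    time_point_min: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (echo, row, col)")
        if self.data.shape[0] != self.grid.n_echoes:
            raise ValueError(
                f"stack has {self.data.shape[0]} echoes, grid expects {self.grid.n_echoes}"
            )
        if self.data.shape[1:] != tuple(self.grid.matrix):
            raise ValueError(
                f"image shape {self.data.shape[1:]} != grid matrix {self.grid.matrix}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be nonnegative")


@dataclass
class ProfileStack:
    """Row-averaged 1D profiles: signal[position, echo] along the stack axis."""

    signal: np.ndarray  # (position, echo), a.u.
    positions_mm: np.ndarray
    segment: tuple[int, int]  # (col_start, col_width_px)
    grid: AcquisitionGrid
    time_point_min: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, float)
        self.positions_mm = np.asarray(self.positions_mm, float)
        if self.signal.shape[0] != self.positions_mm.shape[0]:
            raise ValueError("signal row count must equal positions count")
        d = np.diff(self.positions_mm)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("positions_mm must be strictly increasing, uniform")


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: MultiEchoStack, path, extra_meta: dict | None = None) -> Path:
    """Write a stack as a multi-page TIFF plus JSON sidecar; returns TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    meta = {
        "grid": stack.grid.to_dict(),
        "time_point_min": stack.time_point_min,
        **stack.meta,
        **(extra_meta or {}),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def read_stack(
    path,
    te_ms: float | None = None,
    n_echoes: int | None = None,
    fov_mm: tuple[float, float] | None = None,
) -> MultiEchoStack:
    """Read a multi-page TIFF stack; grid from the JSON sidecar or fallback flags.

    Round-trips bit-exactly with :func:`write_stack`.  Without a sidecar,
    ``te_ms`` (and optionally ``n_echoes``/``fov_mm``) must be supplied.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        grid = AcquisitionGrid.from_dict(meta["grid"])
    elif te_ms is not None:
        grid = AcquisitionGrid(
            te_ms=te_ms,
            n_echoes=n_echoes if n_echoes is not None else data.shape[0],
            matrix=data.shape[1:],
            fov_mm=fov_mm if fov_mm is not None else (24.0, 24.0),
        )
    else:
        raise FileNotFoundError(
            f"no sidecar {sidecar} and no fallback te_ms/n_echoes supplied"
        )
    if data.shape[0] != grid.n_echoes:
        raise ValueError(
            f"TIFF has {data.shape[0]} pages but grid expects {grid.n_echoes} echoes"
        )
    extra = {k: v for k, v in meta.items() if k not in ("grid", "time_point_min")}
    return MultiEchoStack(
        data=data,
        grid=grid,
        time_point_min=float(meta.get("time_point_min", 0.0)),
        meta=extra,
    )


def extract_profile(
    stack: MultiEchoStack,
    segment: tuple[int, int] | None = None,
    origin_row: int = 64,
) -> ProfileStack:
    """Average a vertical pixel segment row-wise into 1D profiles per echo.

    ``segment`` is (col_start, width_px); the default is a 10-pixel-wide
    band centered in the image.  Each profile row is the arithmetic mean
    of the segment's pixels in that image row.  L coordinates follow the
    pixel-center convention with L = 0 at the top edge of ``origin_row``
    (the designated top-of-dressing row).
    """
    n_rows, n_cols = stack.grid.matrix
    if segment is None:
        segment = (n_cols // 2 - 5, 10)
    col_start, width = segment
    if width < 1:
        raise ValueError("segment width must be >= 1")
    if col_start < 0 or col_start + width > n_cols:
        raise ValueError(f"segment {segment} outside image with {n_cols} columns")
    sig = stack.data[:, :, col_start:col_start + width].mean(axis=2).T  # (row, echo)
    pix = stack.grid.pixel_mm[0]
    positions = (np.arange(n_rows) - origin_row + 0.5) * pix
    return ProfileStack(
        signal=sig,
        positions_mm=positions,
        segment=segment,
        grid=stack.grid,
        time_point_min=stack.time_point_min,
    )


@dataclass
class ReferenceReport:
    """Constancy check of the reference-compartment signal across scans."""

    time_points_min: list[float]
    amplitudes: list[float]
    t2_ms: list[float]
    max_rel_deviation: float
    threshold: float
    passed: bool


def reference_check(
    stack_series: list[MultiEchoStack],
    ref_region: tuple[int, int, int, int],
    threshold: float = 0.05,
) -> ReferenceReport:
    """Quality check: the reference compartment's amplitude must stay constant.

    ``ref_region`` is (row_start, row_stop, col_start, col_stop).  The
    ROI-mean decay of each stack is fitted mono-exponentially and the
    maximum relative deviation of the fitted amplitude from the series
    mean is compared against ``threshold`` (default 5%).
    """
    from .multiexp import DecayCurve, fit_decay

    if not stack_series:
        raise ValueError("empty stack series")
    r0, r1, c0, c1 = ref_region
    amps, t2s, times = [], [], []
    for stack in stack_series:
        n_rows, n_cols = stack.grid.matrix
        if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
            raise ValueError(f"ref_region {ref_region} outside image {stack.grid.matrix}")
        decay = stack.data[:, r0:r1, c0:c1].mean(axis=(1, 2))
        curve = DecayCurve(
            times_ms=stack.grid.echo_times_ms,
            intensities=decay,
            origin=("reference", stack.time_point_min),
        )
        fit = fit_decay(curve, n=1)
        amps.append(fit.components[0].amplitude)
        t2s.append(fit.components[0].t2_ms)
        times.append(stack.time_point_min)
    amps_arr = np.array(amps)
    mean = amps_arr.mean()
    max_dev = float(np.max(np.abs(amps_arr - mean)) / mean) if mean > 0 else np.inf
    return ReferenceReport(
        time_points_min=times,
        amplitudes=amps,
        t2_ms=t2s,
        max_rel_deviation=max_dev,
        threshold=threshold,
        passed=max_dev <= threshold,
    )


def profile_to_csv(profile: ProfileStack, path, header_comment: str | None = None) -> None:
    """Persist a profile stack as long-format CSV (t_min, L_mm, echo_ms, intensity)."""
    echo_ms = profile.grid.echo_times_ms
    n_pos, n_echo = profile.signal.shape
    df = pd.DataFrame(
        {
            "t_min": np.full(n_pos * n_echo, profile.time_point_min),
            "L_mm": np.repeat(profile.positions_mm, n_echo),
            "echo_ms": np.tile(echo_ms, n_pos),
            "intensity": profile.signal.ravel(),
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# segment={profile.segment[0]}:{profile.segment[1]}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def profile_from_csv(path, grid: AcquisitionGrid) -> ProfileStack:
    df = pd.read_csv(path, comment="#")
    positions = np.sort(df["L_mm"].unique())
    echo_ms = np.sort(df["echo_ms"].unique())
    piv = df.pivot_table(index="L_mm", columns="echo_ms", values="intensity")
    piv = piv.reindex(index=positions, columns=echo_ms)
    return ProfileStack(
        signal=piv.to_numpy(),
        positions_mm=positions,
        segment=(0, 1),
        grid=grid,
        time_point_min=float(df["t_min"].iloc[0]),
    )
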