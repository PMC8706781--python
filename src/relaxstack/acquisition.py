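"""Acquisition geometry of a multi-slice multi-echo (MSME) T2-weighted series.

An MSME acquisition produces one magnitude image per echo; the k-th image
samples the transverse decay at t = k*TE.  The default grid reproduces the
9.4 T protocol used throughout this package: TE = 3.644 ms, 256 echoes,
256x256 matrix over a 24x24 mm^2 field of view (0.094 mm in-plane pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionGrid"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Echo timing and image geometry of a multi-echo acquisition.

    Parameters
    ----------
    te_ms
        Echo spacing in milliseconds; echo k (1-based) is sampled at k*te_ms.
    n_echoes
        Number of echoes in the train.
    matrix
        Image matrix as (rows, cols).
    fov_mm
        Field of view as (height, width) in millimetres.
    """

    te_ms: float = 3.644
    n_echoes: int = 256
    matrix: tuple[int, int] = (256, 256)
    fov_mm: tuple[float, float] = (24.0, 24.0)

    def __post_init__(self) -> None:
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if any(m < 1 for m in self.matrix):
            raise ValueError("matrix dimensions must be >= 1")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("fov_mm must be positive")

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Echo sampling times k*TE, k = 1..n_echoes (strictly increasing)."""
        return self.te_ms * np.arange(1, self.n_echoes + 1)

    @property
    def pixel_mm(self) -> tuple[float, float]:
        """Exact pixel size (row, col) = fov / matrix, in mm."""
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def pixel_mm_display(self) -> tuple[float, float]:
        """Pixel size rounded to 3 decimals for display (24/256 -> 0.094)."""
        return (round(self.pixel_mm[0], 3), round(self.pixel_mm[1], 3))

    def to_dict(self) -> dict:
        return {
            "te_ms": self.te_ms,
            "n_echoes": self.n_echoes,
            "matrix": list(self.matrix),
            "fov_mm": list(self.fov_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGrid":
        return cls(
            te_ms=float(d["te_ms"]),
            n_echoes=int(d["n_echoes"]),
            matrix=tuple(int(x) for x in d["matrix"]),
            fov_mm=tuple(float(x) for x in d["fov_mm"]),
        )
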