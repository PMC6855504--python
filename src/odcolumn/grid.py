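"""Simulation grid: a 2D cortical patch sampled at native resolution plus time.

Conventions used throughout the package:

* lengths in mm, times in s;
* cell-centered samples, origin at the patch center, so the i-th sample
  along x sits at ``x_i = (i + 1/2) h - extent_x / 2``;
* arrays are indexed ``(x, y)`` row-major, time on the last axis;
* the Fourier dual carries angular frequencies ``k`` in rad/mm and
  ``omega`` in rad/s, laid out in numpy ``fftfreq`` order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import InvalidParameterError

#: Finest in-plane acquisition resolution the package analyses (mm). The
#: native grid must be at least this fine so every supported voxel size can
#: be emulated by k-space filtering of the native field.
FINEST_RESOLUTION = 0.125

_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Native sampling of the cortical patch in space and time.

    Parameters
    ----------
    nx, ny:
        Sample counts along x and y.
    h:
        Native sample spacing in mm. Must not exceed ``FINEST_RESOLUTION``.
    nt:
        Number of time samples.
    dt:
        Time step in s. The default protocol (23 s window, 0.1 s step)
        places the stimulus onset/offset (3 s, 10 s) and the 9.7 s
        measurement snapshot exactly on the time grid.
    """

    nx: int
    ny: int
    h: float
    nt: int = 230
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nt < 1:
            raise InvalidParameterError("grid sample counts must be >= 1")
        if not self.h > 0:
            raise InvalidParameterError("native spacing h must be positive")
        if self.h > FINEST_RESOLUTION + _TOL:
            raise InvalidParameterError(
                f"native spacing h={self.h} mm is coarser than the finest "
                f"analysis resolution {FINEST_RESOLUTION} mm"
            )
        if not self.dt > 0:
            raise InvalidParameterError("time step dt must be positive")

    @classmethod
    def from_extent(
        cls,
        extent_x: float,
        extent_y: float,
        h: float = FINEST_RESOLUTION,
        duration: float = 23.0,
        dt: float = 0.1,
    ) -> "GridSpec":
        """Build a grid from physical extents; extents must be multiples of h."""
        nx = int(round(extent_x / h))
        ny = int(round(extent_y / h))
        nt = int(round(duration / dt))
        if abs(nx * h - extent_x) > _TOL or abs(ny * h - extent_y) > _TOL:
            raise InvalidParameterError("extents must be integer multiples of h")
        if abs(nt * dt - duration) > _TOL:
            raise InvalidParameterError("duration must be an integer multiple of dt")
        return cls(nx=nx, ny=ny, h=h, nt=nt, dt=dt)

    # -- physical coordinates -------------------------------------------------

    @property
    def extent_x(self) -> float:
        return self.nx * self.h

    @property
    def extent_y(self) -> float:
        return self.ny * self.h

    @property
    def duration(self) -> float:
        return self.nt * self.dt

    @cached_property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.h - self.extent_x / 2

    @cached_property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.h - self.extent_y / 2

    @cached_property
    def t(self) -> np.ndarray:
        return np.arange(self.nt) * self.dt

    # -- Fourier dual ---------------------------------------------------------

    @cached_property
    def kx(self) -> np.ndarray:
        return 2 * np.pi * np.fft.fftfreq(self.nx, d=self.h)

    @cached_property
    def ky(self) -> np.ndarray:
        return 2 * np.pi * np.fft.fftfreq(self.ny, d=self.h)

    @cached_property
    def omega(self) -> np.ndarray:
        return 2 * np.pi * np.fft.fftfreq(self.nt, d=self.dt)

    def k_squared(self) -> np.ndarray:
        """|k|^2 on the (nx, ny) spatial-frequency grid."""
        return self.kx[:, None] ** 2 + self.ky[None, :] ** 2

    # -- lookups --------------------------------------------------------------

    def spatial_shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nt)

    def time_index(self, t: float) -> int:
        """Index of the time sample at ``t``; ``t`` must lie on the grid."""
        idx = int(round(t / self.dt))
        if not (0 <= idx < self.nt) or abs(idx * self.dt - t) > _TOL:
            raise InvalidParameterError(f"t={t} s is not a grid time sample")
        return idx

    def nearest_index(self, x: float, y: float) -> tuple[int, int]:
        """Indices of the sample whose cell contains (x, y)."""
        from .errors import DomainError

        hx, hy = self.extent_x / 2, self.extent_y / 2
        if not (-hx - _TOL <= x <= hx + _TOL and -hy - _TOL <= y <= hy + _TOL):
            raise DomainError(f"point ({x}, {y}) mm outside the patch")
        i = min(int(np.floor((x + hx) / self.h)), self.nx - 1)
        j = min(int(np.floor((y + hy) / self.h)), self.ny - 1)
        return max(i, 0), max(j, 0)
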