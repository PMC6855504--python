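"""Idealized ocular-dominance / orientation-preference map of V1.

The map is built from a fundamental 2a x 2a block containing four
orientation pinwheels (one per quadrant, adjacent ones of opposite
handedness) and vertical ocular-dominance stripes of width a/2, and can be
tiled periodically to cover an arbitrarily large cortical patch. With the
default hypercolumn width a = 2 mm, a 3x3 tiling of blocks gives the
standard 12 mm x 12 mm patch of 36 hypercolumn cells.

The orientation angle in the first-quadrant cell is

    phi(x, y) = (1/2) [ atan2(y - y0, x - x0) + pi ]   (mod pi),

with the pinwheel center at (x0, y0) = (a/2, a/2); the other quadrants
follow by reflection across the x- and/or y-axes, a reflection mapping
phi -> pi - phi (mod pi) so that adjacent pinwheels have opposite chirality.
Ocular dominance alternates in vertical stripes of width a/2 with a left/right
boundary at x = 0 (label L for x mod a in [0, a/2), R otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError

#: Hypercolumn (unit-cell) width in mm: one left-eye plus one right-eye
#: stripe of 1 mm each.
DEFAULT_CELL_WIDTH = 2.0

#: Eye labels encoded in the ``od`` array.
LEFT, RIGHT = 0, 1

_TOL = 1e-9


def op_angle(x, y, a: float = DEFAULT_CELL_WIDTH):
    """Orientation-preference angle in [0, pi) at position(s) (x, y) mm.

    Vectorized closed form of the pinwheel construction, periodic with
    period 2a in both axes. The singular pinwheel centers are assigned
    phi = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # wrap into the fundamental block [-a, a)
    xw = np.mod(x + a, 2 * a) - a
    yw = np.mod(y + a, 2 * a) - a
    u = np.abs(xw)
    v = np.abs(yw)
    du = u - a / 2
    dv = v - a / 2
    phi = np.mod(0.5 * (np.arctan2(dv, du) + np.pi), np.pi)
    reflected = (xw < 0) ^ (yw < 0)
    phi = np.where(reflected, np.mod(np.pi - phi, np.pi), phi)
    # pinwheel-center singularity: defined as 0
    phi = np.where((du == 0) & (dv == 0), 0.0, phi)
    return phi


def od_label(x, a: float = DEFAULT_CELL_WIDTH):
    """Eye label (LEFT=0 / RIGHT=1) of the vertical stripe containing x."""
    x = np.asarray(x, dtype=float)
    return np.where(np.mod(x, a) < a / 2, LEFT, RIGHT).astype(np.int8)


@dataclass(frozen=True)
class FeatureMap:
    """Per-sample OP angle and OD eye label over a 2D cortical patch.

    ``op[i, j]`` and ``od[i, j]`` are the values at ``(x[i], y[j])``.
    """

    x: np.ndarray
    y: np.ndarray
    op: np.ndarray
    od: np.ndarray
    a: float
    h: float

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def extent_x(self) -> float:
        return self.nx * self.h

    @property
    def extent_y(self) -> float:
        return self.ny * self.h

    @property
    def x0(self) -> float:
        """x of the first (top-right) pinwheel center."""
        return self.a / 2

    @property
    def y0(self) -> float:
        return self.a / 2


def build_unit_cell(a: float = DEFAULT_CELL_WIDTH, h: float = 0.125) -> FeatureMap:
    """Construct the fundamental 2a x 2a block on coordinates [-a, a].

    ``h`` must divide ``a`` so stripe and cell boundaries fall between
    samples consistently.
    """
    if not a > 0:
        raise InvalidParameterError("cell width a must be positive")
    if not h > 0:
        raise InvalidParameterError("sample spacing h must be positive")
    n_half = a / h
    if abs(n_half - round(n_half)) > _TOL:
        raise InvalidParameterError("h must divide the cell width a")
    n = int(round(2 * a / h))
    x = (np.arange(n) + 0.5) * h - a
    y = (np.arange(n) + 0.5) * h - a
    op = op_angle(x[:, None], y[None, :], a=a)
    od = np.broadcast_to(od_label(x, a=a)[:, None], (n, n)).copy()
    return FeatureMap(x=x, y=y, op=op, od=od, a=a, h=h)


def tile_cells(cell: FeatureMap, mcells_x: int, mcells_y: int) -> FeatureMap:
    """Tile the 2a x 2a block ``mcells_x`` x ``mcells_y`` times.

    A 1x1 tiling returns a map equal to the input block. The default
    12 mm x 12 mm experiment map is a 3x3 tiling (36 hypercolumn cells at
    a = 2 mm); see :func:`build_map`.
    """
    if int(mcells_x) != mcells_x or int(mcells_y) != mcells_y:
        raise InvalidParameterError("tile counts must be integers")
    if mcells_x < 1 or mcells_y < 1:
        raise InvalidParameterError("tile counts must be >= 1")
    mcells_x, mcells_y = int(mcells_x), int(mcells_y)
    op = np.tile(cell.op, (mcells_x, mcells_y))
    od = np.tile(cell.od, (mcells_x, mcells_y))
    nx, ny = op.shape
    x = (np.arange(nx) + 0.5) * cell.h - nx * cell.h / 2
    y = (np.arange(ny) + 0.5) * cell.h - ny * cell.h / 2
    return FeatureMap(x=x, y=y, op=op, od=od, a=cell.a, h=cell.h)


def build_map(
    a: float = DEFAULT_CELL_WIDTH, h: float = 0.125, blocks: int = 3
) -> FeatureMap:
    """Default experiment map: ``blocks`` x ``blocks`` fundamental blocks.

    blocks=3 with a = 2 mm gives the 12 mm x 12 mm patch of 36 hypercolumn
    cells used throughout the resolution and sensitivity studies.
    """
    return tile_cells(build_unit_cell(a=a, h=h), blocks, blocks)


def query(fmap: FeatureMap, x: float, y: float) -> tuple[float, int]:
    """Nearest-sample lookup of (OP angle, OD label) at a point in mm."""
    hx, hy = fmap.extent_x / 2, fmap.extent_y / 2
    if not (-hx - _TOL <= x <= hx + _TOL and -hy - _TOL <= y <= hy + _TOL):
        raise DomainError(f"query point ({x}, {y}) mm outside the map")
    i = int(np.clip(np.floor((x + hx) / fmap.h), 0, fmap.nx - 1))
    j = int(np.clip(np.floor((y + hy) / fmap.h), 0, fmap.ny - 1))
    return float(fmap.op[i, j]), int(fmap.od[i, j])
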