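"""Scanner-resolution degradation: k-space filtering, noise, pixelation.

A continuous (native-grid) field is degraded to an in-plane voxel size
``dx`` by zeroing all Fourier modes with |k| >= k_c = pi / dx (the "2 pi /
(2 dx)" cutoff; an isotropic sharp window, i.e. sinc smoothing in
coordinate space). Measurement noise is modelled as Gaussian spatial white
noise generated at native resolution, passed through the same k-space
filter as the signal, and normalized so its post-filter rms equals

    sigma = signal_ref / (snr0 (dx / 1 mm)^2),

the task-based SNR calibration snr0 = 200 at 1 mm for voxels of size
dx x dx x 3 mm. The noise model is purely spatial — one frozen field
corrupts every time frame. ``signal_ref`` defaults to the spatial peak of
the noise-free smoothed BOLD at the measurement snapshot. Finally the smoothed
field is discretized by sampling at the centers of a voxel grid anchored
at the patch corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InvalidParameterError
from .grid import GridSpec
from .hemodynamics import SNAPSHOT_TIME, BoldField

_TOL = 1e-9

#: Through-plane slice thickness (mm) assumed by the SNR calibration.
SLICE_THICKNESS = 3.0


@dataclass(frozen=True)
class AcquisitionParams:
    """In-plane voxel size, SNR calibration and noise switches."""

    dx: float
    snr0: float = 200.0
    seed: int | None = None
    add_noise: bool = True
    signal_ref: float | None = None  # None: peak of smoothed field at snapshot
    t_snapshot: float = SNAPSHOT_TIME

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise InvalidParameterError("voxel size dx must be positive")
        if not self.snr0 > 0:
            raise InvalidParameterError("snr0 must be positive")


@dataclass(frozen=True)
class VoxelImage:
    """Pixelated image sequence plus the smoothed (unpixelated) field.

    ``values`` has one sample per voxel per time frame; ``smoothed`` is the
    band-limited field on the native grid before pixelation (and after
    noise injection, if any). ``sigma`` is the injected noise rms (None
    when noise was disabled).
    """

    dx: float
    origin: tuple[float, float]  # patch corner, mm
    values: np.ndarray  # (nvx, nvy, nt)
    grid: GridSpec  # native grid the image was acquired from
    smoothed: np.ndarray  # (nx, ny, nt)
    sigma: float | None
    signal_ref: float


def cutoff_wavenumber(dx: float) -> float:
    """k_c = 2 pi / (2 dx) = pi / dx, in rad/mm."""
    return np.pi / dx


def _passband(grid: GridSpec, dx: float) -> np.ndarray:
    return grid.k_squared() < cutoff_wavenumber(dx) ** 2


def kspace_lowpass(field: np.ndarray, dx: float, grid: GridSpec) -> np.ndarray:
    """Zero all spatial-frequency modes with |k| >= pi/dx.

    ``field`` may be 2D (nx, ny) or 3D (nx, ny, nt); filtering acts on the
    first two axes, frame by frame. Idempotent; the DC mode always passes.
    """
    if dx < grid.h - _TOL:
        raise InvalidParameterError(
            f"voxel size dx={dx} mm finer than the native grid h={grid.h} mm"
        )
    if field.shape[:2] != grid.spatial_shape():
        raise GridMismatchError("field shape does not match the grid")
    mask = _passband(grid, dx)
    if field.ndim == 3:
        mask = mask[:, :, None]
    fk = np.fft.fft2(field, axes=(0, 1))
    out = np.fft.ifft2(fk * mask, axes=(0, 1))
    return np.ascontiguousarray(out.real)


def noise_sigma(dx: float, snr0: float, signal_ref: float) -> float:
    """Noise rms from the task-based SNR calibration snr0 * (dx/1mm)^2."""
    if dx <= 0 or snr0 <= 0 or signal_ref <= 0:
        raise InvalidParameterError("dx, snr0 and signal_ref must be positive")
    return signal_ref / (snr0 * dx**2)


def make_noise(
    grid: GridSpec,
    params: AcquisitionParams,
    sigma: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Band-limited spatial white noise field with post-filter rms ``sigma``.

    A single 2D Gaussian white field at native resolution, k-space
    filtered at the cutoff for ``params.dx`` and scaled analytically by
    the kept-mode fraction so the expected rms equals ``sigma``. The noise
    model is purely spatial: the same frozen field corrupts every time
    frame (the measurement-noise budget of a task-based acquisition is
    expressed per spatial image), so callers broadcast the returned
    (nx, ny) array over time.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    white = rng.standard_normal(grid.spatial_shape())
    mask = _passband(grid, params.dx)
    kept = mask.mean()
    fk = np.fft.fft2(white) * mask
    filtered = np.fft.ifft2(fk).real
    return np.ascontiguousarray(filtered * (sigma / np.sqrt(kept)))


def pixelate(field: np.ndarray, dx: float, grid: GridSpec) -> tuple[np.ndarray, tuple[float, float]]:
    """Sample a native-grid field at voxel centers.

    The voxel grid is anchored at the patch corner; each voxel takes the
    value of the native sample containing its center (for ``dx`` an even
    multiple of ``h`` the center falls on a native cell boundary and the
    sample on its +side is used). Returns the voxel array and the corner
    origin in mm.
    """
    nvx = int(np.floor(grid.extent_x / dx + _TOL))
    nvy = int(np.floor(grid.extent_y / dx + _TOL))
    ox, oy = -grid.extent_x / 2, -grid.extent_y / 2
    cx = ox + (np.arange(nvx) + 0.5) * dx
    cy = oy + (np.arange(nvy) + 0.5) * dx
    ix = np.clip(np.floor((cx - ox) / grid.h).astype(int), 0, grid.nx - 1)
    iy = np.clip(np.floor((cy - oy) / grid.h).astype(int), 0, grid.ny - 1)
    return field[np.ix_(ix, iy)], (ox, oy)


def acquire(Y: BoldField, params: AcquisitionParams) -> VoxelImage:
    """Full acquisition: smooth, optionally add calibrated noise, pixelate."""
    grid = Y.grid
    smoothed = kspace_lowpass(Y.values, params.dx, grid)
    if params.signal_ref is not None:
        signal_ref = params.signal_ref
    else:
        it = grid.time_index(params.t_snapshot)
        signal_ref = float(np.abs(smoothed[:, :, it]).max())
    sigma = None
    if params.add_noise:
        sigma = noise_sigma(params.dx, params.snr0, signal_ref)
        smoothed = smoothed + make_noise(grid, params, sigma)[:, :, None]
    values, origin = pixelate(smoothed, params.dx, grid)
    return VoxelImage(
        dx=params.dx,
        origin=origin,
        values=values,
        grid=grid,
        smoothed=smoothed,
        sigma=sigma,
        signal_ref=signal_ref,
    )


def upsample_to_native(vox: VoxelImage) -> np.ndarray:
    """Zero-order-hold resampling of a voxel image back onto its native grid."""
    grid = vox.grid
    ox, oy = vox.origin
    jx = np.clip(((grid.x - ox) / vox.dx).astype(int), 0, vox.values.shape[0] - 1)
    jy = np.clip(((grid.y - oy) / vox.dx).astype(int), 0, vox.values.shape[1] - 1)
    return vox.values[np.ix_(jx, jy)]
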