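"""Readers and writers: NIfTI-1 fields, JSON sidecars, HDF5 spectra, CSV.

2D+t fields are stored as X x Y x 1 x T NIfTI-1 volumes with pixdim
(h, h, slice, dt) and mm/s units; the feature map as a 2-layer volume
(OP in radians, OD as 0/1). Every NIfTI gets a JSON sidecar carrying the
generating parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import SLICE_THICKNESS
from .cortexmap import FeatureMap
from .grid import GridSpec
from .hemodynamics import TransferFunction


def _affine(dx: float, dy: float) -> np.ndarray:
    return np.diag([dx, dy, SLICE_THICKNESS, 1.0])


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_sidecar(path, meta: dict) -> Path:
    out = sidecar_path(path)
    out.write_text(json.dumps(meta, indent=2, sort_keys=True, default=float))
    return out


def read_sidecar(path) -> dict:
    return json.loads(sidecar_path(path).read_text())


def write_field(
    path,
    values: np.ndarray,
    dx: float,
    dt: float = 0.1,
    meta: dict | None = None,
) -> Path:
    """Write an (nx, ny[, nt]) field as an X x Y x 1 x T NIfTI-1 file."""
    path = Path(path)
    data = np.asarray(values, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    img_data = data[:, :, None, :]
    img = nib.Nifti1Image(img_data, _affine(dx, dx))
    img.header.set_zooms((dx, dx, SLICE_THICKNESS, dt))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    if meta is not None:
        write_sidecar(path, meta)
    return path


def read_field(path) -> tuple[np.ndarray, float, float]:
    """Read an X x Y x 1 x T NIfTI back as ((nx, ny, nt), dx, dt)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    zooms = img.header.get_zooms()
    dx = float(zooms[0])
    dt = float(zooms[3]) if len(zooms) > 3 else 0.0
    return data, dx, dt


def write_feature_map(fmap: FeatureMap, path, meta: dict | None = None) -> Path:
    """Feature map as a 2-layer NIfTI (OP radians, OD 0/1) + JSON sidecar."""
    path = Path(path)
    data = np.stack([fmap.op, fmap.od.astype(float)], axis=-1)[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float32), _affine(fmap.h, fmap.h))
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    base = dict(a=fmap.a, h=fmap.h, extent_x=fmap.extent_x,
                extent_y=fmap.extent_y, x0=fmap.x0, y0=fmap.y0,
                layers=["op_radians", "od_label"])
    write_sidecar(path, {**base, **(meta or {})})
    return path


def read_feature_map(path) -> FeatureMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)[:, :, 0, :]
    meta = read_sidecar(path)
    h, a = float(meta["h"]), float(meta["a"])
    nx, ny = data.shape[:2]
    x = (np.arange(nx) + 0.5) * h - nx * h / 2
    y = (np.arange(ny) + 0.5) * h - ny * h / 2
    return FeatureMap(x=x, y=y, op=data[:, :, 0],
                      od=data[:, :, 1].astype(np.int8), a=a, h=h)


def write_transfer_function(H: TransferFunction, path) -> Path:
    """Dump H(k, omega) to HDF5 for inspection."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=H.values.real, compression="gzip")
        f.create_dataset("imag", data=H.values.imag, compression="gzip")
        f.create_dataset("kx", data=H.grid.kx)
        f.create_dataset("ky", data=H.grid.ky)
        f.create_dataset("omega", data=H.grid.omega)
        for key in ("gamma", "nu_beta", "gain"):
            f.attrs[key] = getattr(H.params, key)
        f.attrs["kappa"] = H.params.kappa_eff
    return path


def grid_meta(grid: GridSpec) -> dict:
    return dict(nx=grid.nx, ny=grid.ny, h=grid.h, nt=grid.nt, dt=grid.dt,
                extent_x=grid.extent_x, extent_y=grid.extent_y,
                duration=grid.duration)
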