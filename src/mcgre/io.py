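"""File I/O: HDF5 k-space container and NIfTI image volumes.

K-space bundles are stored in an HDF5 file with fixed dataset names:

* ``/samples``    complex, shape (4, n_coils, n_samples) in the canonical
  (echo, pass) order UTE+/UTE-/CTE+/CTE-
* ``/trajectory`` float, the coordinate array (cycles/sample)
* ``/coil_maps``  complex, shape (n_coils, *grid)
* ``/meta``       a JSON string (sequence parameters, trajectory mode,
  seeds, noise level, package version)

Complex image volumes are written to NIfTI as a real/imaginary pair stacked
along a trailing axis of length 2 (shape (*grid, 2)); real volumes are
written as-is.  Round trips are bit-exact for HDF5 and float64-exact for
NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import nibabel as nib
import numpy as np

from .encoding import Trajectory
from .phantom import CoilMaps

_REQUIRED_DATASETS = ("samples", "trajectory", "coil_maps", "meta")


class ContainerFormatError(ValueError):
    """Malformed k-space container; the message names the offending dataset."""


@dataclass
class KSpaceBundle:
    """Four (echo, pass) k-space datasets plus everything needed to recon them."""

    samples: np.ndarray  # (4, n_coils, n_samples)
    traj: Trajectory
    coils: CoilMaps
    meta: dict

    def __post_init__(self) -> None:
        if self.samples.ndim != 3 or self.samples.shape[0] != 4:
            raise ValueError("samples must have shape (4, n_coils, n_samples)")
        if self.samples.shape[2] != self.traj.n_samples_total:
            raise ValueError("sample count does not match the trajectory")
        if self.samples.shape[1] != self.coils.n_coils:
            raise ValueError("coil count mismatch")


def save_kspace(path, bundle: KSpaceBundle) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=bundle.samples)
        traj_ds = f.create_dataset("trajectory", data=bundle.traj.coords)
        traj_ds.attrs["mode"] = bundle.traj.mode
        f.create_dataset("coil_maps", data=bundle.coils.maps)
        f.create_dataset("meta", data=json.dumps(bundle.meta))


def load_kspace(path) -> KSpaceBundle:
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise ContainerFormatError(f"missing dataset /{name}")
        coords = np.asarray(f["trajectory"])
        mode = f["trajectory"].attrs.get("mode", "radial_golden")
        traj = Trajectory(coords=coords, mode=str(mode))
        coils = CoilMaps(maps=np.asarray(f["coil_maps"]))
        try:
            meta = json.loads(f["meta"][()])
        except json.JSONDecodeError as err:
            raise ContainerFormatError(f"dataset /meta is not valid JSON: {err}") from err
        return KSpaceBundle(
            samples=np.asarray(f["samples"]), traj=traj, coils=coils, meta=meta
        )


def save_nifti(path, volume: np.ndarray, voxel_mm: float = 1.0) -> None:
    """Write a real or complex volume; complex goes out as (*grid, 2)."""
    if np.iscomplexobj(volume):
        data = np.stack([volume.real, volume.imag], axis=-1)
    else:
        data = np.asarray(volume, dtype=float)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine=affine), str(path))


def load_nifti(path, complex_pair: bool = False) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    if complex_pair:
        if data.shape[-1] != 2:
            raise ValueError("expected a trailing real/imag axis of length 2")
        return data[..., 0] + 1j * data[..., 1]
    return data
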