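"""Volume file formats: TIFF stacks, MRC/CCP4 maps and HDF5.

The voxel size travels with the file: in the MRC header (cell / sampling),
in HDF5 attributes, and in a JSON sidecar (``<file>.json``) for TIFF.
A volume without a recoverable voxel size raises :class:`MetadataError`
rather than assuming a default.

Grids are stored in the package's ``[x, y, z]`` axis order; TIFF pages are
z-slices (``(z, y, x)`` on disk), transposed transparently.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import h5py
import numpy as np
import tifffile

from .exceptions import MetadataError
from .volume import VoxelVolume

__all__ = ["read_volume", "write_volume"]

_TIFF = {".tif", ".tiff"}
_MRC = {".mrc", ".map", ".ccp4"}
_HDF5 = {".h5", ".hdf5", ".hdf"}

# MRC header words holding the map origin (Å), 1-based
_MRC_ORIGIN_WORDS = (50, 51, 52)


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a volume; the format follows the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        tifffile.imwrite(path, np.transpose(volume.grid, (2, 1, 0)))
        sidecar = {
            "voxel_nm": float(volume.voxel_nm),
            "origin_um": [float(v) for v in volume.origin_um],
            "axis_order": "zyx pages",
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    elif suffix in _MRC:
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.grid, dtype=np.float32))
        edge_A = volume.voxel_nm * 10.0  # 1 nm = 10 Å
        m.grid.unit_cell = gemmi.UnitCell(
            volume.grid.shape[0] * edge_A,
            volume.grid.shape[1] * edge_A,
            volume.grid.shape[2] * edge_A,
            90.0, 90.0, 90.0,
        )
        m.update_ccp4_header()
        for word, val in zip(_MRC_ORIGIN_WORDS, volume.origin_um):
            m.set_header_float(word, float(val * 1.0e4))  # µm -> Å
        m.write_ccp4_map(str(path))
    elif suffix in _HDF5:
        with h5py.File(path, "w") as f:
            f.create_dataset("grid", data=volume.grid, compression="gzip")
            f.attrs["voxel_nm"] = float(volume.voxel_nm)
            f.attrs["origin_um"] = [float(v) for v in volume.origin_um]
    else:
        raise MetadataError(f"unsupported volume format: {path.suffix}")


def read_volume(path) -> VoxelVolume:
    """Read a volume written by :func:`write_volume` (or compatible files)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise MetadataError(
                f"TIFF volume {path.name} has no voxel-size sidecar "
                f"({sidecar.name}); refusing to guess"
            )
        meta = json.loads(sidecar.read_text())
        if "voxel_nm" not in meta:
            raise MetadataError(f"sidecar {sidecar.name} lacks voxel_nm")
        data = tifffile.imread(path)
        grid = np.transpose(data, (2, 1, 0))
        return VoxelVolume(grid, float(meta["voxel_nm"]),
                           np.asarray(meta.get("origin_um", (0, 0, 0)), dtype=float))
    if suffix in _MRC:
        m = gemmi.read_ccp4_map(str(path))
        spacing_A = m.grid.spacing[0]
        if not spacing_A > 0:
            raise MetadataError(f"MRC map {path.name} has no voxel size in its header")
        grid = np.array(m.grid, copy=True)
        origin = np.array([m.header_float(w) for w in _MRC_ORIGIN_WORDS]) * 1.0e-4
        return VoxelVolume(grid, spacing_A / 10.0, origin)
    if suffix in _HDF5:
        with h5py.File(path, "r") as f:
            if "voxel_nm" not in f.attrs:
                raise MetadataError(f"HDF5 volume {path.name} lacks a voxel_nm attribute")
            return VoxelVolume(
                f["grid"][...],
                float(f.attrs["voxel_nm"]),
                np.asarray(f.attrs.get("origin_um", (0.0, 0.0, 0.0)), dtype=float),
            )
    raise MetadataError(f"unsupported volume format: {path.suffix}")
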