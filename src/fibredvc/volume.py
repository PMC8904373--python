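"""3D greyscale volume container and TIFF/HDF5 IO.

Convention used throughout the package: arrays are indexed ``[x, y, z]``,
0-based, with ``z`` the specimen height / compression axis and ``y`` the
lamella stacking (depth) axis.  Physical position in µm is
``index * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A greyscale image volume with physical voxel size.

    Parameters
    ----------
    data:
        3D array indexed ``[x, y, z]``.  Stored as given (typically uint16
        for phantoms, matching 16-bit tomographic exports).
    voxel_size:
        Edge length of one voxel in µm.
    valid:
        Optional boolean mask flagging voxels with trustworthy intensities;
        resampling marks voxels whose interpolation stencil left the source
        domain as invalid.
    """

    data: np.ndarray
    voxel_size: float = 1.625
    valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def as_float(self) -> np.ndarray:
        """Contiguous float64 view of the data for interpolation kernels."""
        return np.ascontiguousarray(self.data, dtype=np.float64)

    def to_um(self, voxel_coords: np.ndarray) -> np.ndarray:
        return np.asarray(voxel_coords, dtype=float) * self.voxel_size

    def to_voxels(self, um_coords: np.ndarray) -> np.ndarray:
        return np.asarray(um_coords, dtype=float) / self.voxel_size


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume to multi-page TIFF (one page per z-slice) or HDF5.

    The format is chosen by extension: ``.h5``/``.hdf5`` for HDF5 (dataset
    ``volume``, attributes ``voxel_size_um`` and ``axis_order``), anything
    else as TIFF with the voxel size in the ImageJ-style resolution tags.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=vol.data, compression="gzip", compression_opts=1)
            ds.attrs["voxel_size_um"] = vol.voxel_size
            ds.attrs["axis_order"] = "xyz"
            if vol.valid is not None:
                f.create_dataset("valid", data=vol.valid.astype(np.uint8), compression="gzip", compression_opts=1)
    else:
        # TIFF pages are z-slices: page axis first, then (y, x) within a page.
        pages = np.transpose(vol.data, (2, 1, 0))
        res = 1.0 / vol.voxel_size
        tifffile.imwrite(path, pages, resolution=(res, res), metadata={"spacing": vol.voxel_size, "unit": "um", "axes": "ZYX"})


def read_volume(path: str | Path, voxel_size: float | None = None) -> Volume:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            ds = f["volume"]
            data = ds[...]
            vs = float(ds.attrs.get("voxel_size_um", voxel_size or 1.625))
            valid = f["valid"][...].astype(bool) if "valid" in f else None
        return Volume(data, vs, valid)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        vs = voxel_size
        if vs is None:
            try:
                vs = float(tf.imagej_metadata.get("spacing", 1.625))
            except (AttributeError, TypeError):
                vs = 1.625
    return Volume(np.transpose(pages, (2, 1, 0)), vs)
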