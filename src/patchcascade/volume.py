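"""Volumetric container and NIfTI-1 I/O.

A :class:`Volume` is the unit every pipeline stage consumes and produces: a
3D scalar grid (gray-matter density or a sub-box of one) together with its
voxel size in millimetres and a record of where it sits inside the volume it
was cropped from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "load_volume", "save_volume"]


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    data
        3D array of intensities. Stored as float32.
    voxel_size_mm
        Isotropic or per-axis voxel edge length in mm (all entries > 0).
    origin_offset
        Voxel index, in the parent grid, of this volume's (0,0,0) corner.
        ``(0, 0, 0)`` for an uncropped volume; crop operations accumulate it.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    origin_offset: tuple[int, int, int] = field(default=(0, 0, 0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"every extent must be >= 1, got shape {self.data.shape}")
        if np.isscalar(self.voxel_size_mm) or isinstance(self.voxel_size_mm, (int, float)):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive lengths, got {self.voxel_size_mm}")
        self.origin_offset = tuple(int(o) for o in self.origin_offset)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with the voxel size recorded in the header.

    ``.nii.gz`` output is byte-deterministic: the gzip stream is written with
    a zeroed timestamp so identical volumes produce identical files.
    """
    path = Path(path)
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    if path.suffix == ".gz":
        import gzip

        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume` (voxel size from header zooms)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, voxel_size_mm=tuple(float(z) for z in zooms))
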