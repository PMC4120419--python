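"""Core data container for 4-D functional spinal cord series.

Axis convention used throughout the package (documented in the README):
axis 0 runs right -> left, axis 1 runs ventral -> dorsal, axis 2 is the
slice (rostro-caudal) axis and axis 3 is time.  Voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from ._utils import fast_copy


@dataclass
class Volume4D:
    """A 4-D functional series: in-plane grid x slices x time.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, n_slices, n_volumes)
        Signal intensity in arbitrary units.
    voxel_size : tuple of float
        Voxel dimensions in mm, (dx, dy, dz).
    tr : float
        Repetition time (volume acquisition time) in seconds.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.31, 0.31, 4.0)
    tr: float = 3.6

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency of the volume sampling, in Hz."""
        return 0.5 / self.tr

    def slice_data(self, s: int) -> np.ndarray:
        """Return the (nx, ny, n_volumes) series of slice ``s`` (a view)."""
        return self.data[:, :, s, :]

    def copy(self) -> "Volume4D":
        return Volume4D(fast_copy(self.data), self.voxel_size, self.tr)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine())
        img.header.set_zooms(tuple(self.voxel_size) + (self.tr,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume4D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 3.6
        return cls(np.asarray(img.dataobj, dtype=np.float64),
                   tuple(float(z) for z in zooms[:3]), tr)


def volume_times(n_volumes: int, tr: float) -> np.ndarray:
    """Nominal acquisition time of each volume (s), starting at 0."""
    return np.arange(n_volumes) * tr
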