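"""Core 3D image containers and NIfTI I/O.

Volumes are plain numpy arrays with per-axis voxel spacing in millimetres.
World coordinates follow ``index * spacing + origin`` with 0-based voxel
indexing; voxel volume is the product of the three spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Image3D",
    "LabelMap",
    "TissueVolumes",
    "LABEL_LEGEND",
    "read_nifti",
    "write_nifti",
    "read_labelmap",
]

#: Tissue label coding used throughout the package.
LABEL_LEGEND = {0: "background", 1: "GM", 2: "WM", 3: "CSF"}


@dataclass
class Image3D:
    """A 3D scalar volume with voxel spacing metadata.

    Parameters
    ----------
    data:
        3D array of intensities.
    voxel_size_mm:
        Per-axis spacing in mm, strictly positive.
    origin:
        Spatial offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel spacing must be three positive values, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def with_data(self, data: np.ndarray) -> "Image3D":
        """Copy of this image carrying new voxel data on the same grid."""
        return Image3D(data=data, voxel_size_mm=self.voxel_size_mm, origin=self.origin)


@dataclass
class LabelMap:
    """Integer tissue labels on the grid of an :class:`Image3D`."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    legend: dict[int, str] = field(default_factory=lambda: dict(LABEL_LEGEND))
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = np.round(self.labels).astype(np.int16)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover present labels {sorted(missing)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels whose tissue name is in ``names``."""
        codes = [c for c, n in self.legend.items() if n in names]
        if not codes:
            raise KeyError(f"no legend entry for {names}")
        return np.isin(self.labels, codes)


@dataclass
class TissueVolumes:
    """Per-tissue voxel counts and volumes (mm^3)."""

    voxel_count: dict[str, int]
    voxel_volume_mm3: float

    @property
    def volume_mm3(self) -> dict[str, float]:
        return {t: c * self.voxel_volume_mm3 for t, c in self.voxel_count.items()}

    def __getitem__(self, tissue: str) -> float:
        return self.voxel_count[tissue] * self.voxel_volume_mm3


def _affine(voxel_size_mm, origin) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_nifti(path, image: Image3D | LabelMap) -> None:
    """Write a volume or label map as NIfTI-1 with spacing in the header."""
    if isinstance(image, LabelMap):
        data = image.labels.astype(np.int16)
    else:
        data = image.data
    img = nib.Nifti1Image(data, _affine(image.voxel_size_mm, image.origin))
    img.header.set_zooms(image.voxel_size_mm)
    nib.save(img, str(path))


def read_nifti(path) -> Image3D:
    """Load a NIfTI volume as :class:`Image3D` (spacing from the header)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Image3D(np.asarray(img.dataobj, dtype=float), spacing, origin)


def read_labelmap(path, legend: dict[int, str] | None = None) -> LabelMap:
    """Load a NIfTI label volume as :class:`LabelMap`."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    labels = np.asarray(img.dataobj)
    return LabelMap(
        labels.astype(np.int16),
        spacing,
        legend=dict(legend) if legend else dict(LABEL_LEGEND),
        origin=origin,
    )
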