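"""Core voxel containers shared by every stage of the pipeline.

A micro-CT scan of a single maize kernel is an isotropic 3D grayscale grid
(``VoxelVolume``); segmentation turns it into a semantic ``LabelVolume`` over
seven classes: background, the three solid kernel components (seed coat,
endosperm, embryo) and interior air cavities classified by location
(subcutaneous, endosperm, embryo).

Axis convention is ``(slice, row, column)``; the voxel size is a single
micron value because the scans this models are reconstructed isotropically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

# Canonical integer <-> class mapping. The generic "cavity" code is a
# transient state used between thresholding and cavity localization.
BACKGROUND = 0
SEED_COAT = 1
ENDOSPERM = 2
EMBRYO = 3
CAVITY_SUBCUTANEOUS = 4
CAVITY_ENDOSPERM = 5
CAVITY_EMBRYO = 6
CAVITY_GENERIC = 7

CLASS_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    SEED_COAT: "seed_coat",
    ENDOSPERM: "endosperm",
    EMBRYO: "embryo",
    CAVITY_SUBCUTANEOUS: "cavity_subcutaneous",
    CAVITY_ENDOSPERM: "cavity_endosperm",
    CAVITY_EMBRYO: "cavity_embryo",
    CAVITY_GENERIC: "cavity",
}

CAVITY_CLASSES = (CAVITY_SUBCUTANEOUS, CAVITY_ENDOSPERM, CAVITY_EMBRYO)
SOLID_CLASSES = (SEED_COAT, ENDOSPERM, EMBRYO)

#: 26-connectivity structuring element (foreground objects).
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 6-connectivity structuring element (background / cavity duality).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class VoxelVolume:
    """Isotropic 3D grayscale image.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities. 8- or 16-bit unsigned integers, or floats inside the
        declared bit-depth range.
    voxel_size_um : float
        Edge length of one (cubic) voxel, in micrometres.
    provenance : str
        Free-text origin note (scanner export, phantom spec hash, ...).
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def with_data(self, data: np.ndarray, note: str = "") -> "VoxelVolume":
        prov = f"{self.provenance}; {note}" if note else self.provenance
        return replace(self, data=data, provenance=prov)


@dataclass
class LabelVolume:
    """Semantic labelling of a :class:`VoxelVolume`.

    ``labels`` uses the integer codes of :data:`CLASS_NAMES`; ``class_map``
    is carried explicitly so files written to disk stay self-describing.
    """

    labels: np.ndarray
    voxel_size_um: float
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got ndim={self.labels.ndim}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def mask(self, *classes: int) -> np.ndarray:
        """Boolean mask of the union of the given class codes."""
        return np.isin(self.labels, classes)

    @property
    def grain_mask(self) -> np.ndarray:
        """All non-background voxels: the solid hull including cavities."""
        return self.labels != BACKGROUND

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.voxel_size_um, dict(self.class_map))


def ball(radius_vox: int) -> np.ndarray:
    """Euclidean ball structuring element of integer voxel radius."""
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius_vox)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return z * z + y * y + x * x <= r * r


def erode(mask: np.ndarray, radius_vox: int) -> np.ndarray:
    """Binary erosion by a Euclidean ball; radius 0 is the identity."""
    if radius_vox == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=ball(radius_vox))


def dilate(mask: np.ndarray, radius_vox: int) -> np.ndarray:
    if radius_vox == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=ball(radius_vox))
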