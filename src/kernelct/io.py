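"""Reading and writing volumes, labels and tables.

Volumes travel as multi-page TIFF (one page per slice, ascending slice
index) with a YAML sidecar carrying the voxel size in micrometres — TIFF
itself has no reliable 3D voxel-size tag. Label volumes add the
integer-to-class map to the sidecar. A directory of numbered single-slice
TIFFs is accepted on read (the export format of most scanner consoles);
slice order is ascending filename index and gaps are an error.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .volume import CLASS_NAMES, LabelVolume, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "sidecar_path",
]


def sidecar_path(path: Path | str) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".yaml")


def _read_sidecar(path: Path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        return {}
    with sc.open() as fh:
        return yaml.safe_load(fh) or {}


def _load_slice_dir(directory: Path) -> np.ndarray:
    pattern = re.compile(r"(\d+)\.tiff?$", re.IGNORECASE)
    slices: list[tuple[int, Path]] = []
    for p in sorted(directory.iterdir()):
        m = pattern.search(p.name)
        if m:
            slices.append((int(m.group(1)), p))
    if not slices:
        raise FileNotFoundError(f"no numbered .tif slices in {directory}")
    slices.sort()
    indices = [i for i, _ in slices]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"slice stack has gaps at indices {missing}")
    arrays = [tifffile.imread(p) for _, p in slices]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    dtypes = {a.dtype for a in arrays}
    if len(dtypes) > 1:
        raise ValueError(f"mixed slice bit depths: {sorted(map(str, dtypes))}")
    return np.stack(arrays, axis=0)


def read_volume(path: Path | str, voxel_size_um: float | None = None) -> VoxelVolume:
    """Load a grayscale volume from a multi-page TIFF or slice directory.

    The voxel size comes from the YAML sidecar unless overridden; with
    neither available this fails loudly rather than guessing.
    """
    path = Path(path)
    if path.is_dir():
        data = _load_slice_dir(path)
        meta = _read_sidecar(path / "volume")
    else:
        data = tifffile.imread(path)
        meta = _read_sidecar(path)
    if data.ndim == 2:
        data = data[None]
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"expected 8- or 16-bit unsigned data, got {data.dtype}")
    vs = voxel_size_um if voxel_size_um is not None else meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(
            f"voxel size unknown for {path}: provide voxel_size_um or a "
            f"{sidecar_path(path).name} sidecar"
        )
    return VoxelVolume(data, float(vs), provenance=str(path))


def write_volume(volume: VoxelVolume, path: Path | str) -> Path:
    """Write a multi-page TIFF plus YAML sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(volume.data))
    meta = {
        "voxel_size_um": float(volume.voxel_size_um),
        "shape": [int(n) for n in volume.shape],
        "dtype": str(volume.data.dtype),
        "provenance": volume.provenance,
    }
    with sidecar_path(path).open("w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def write_labels(labels: LabelVolume, path: Path | str) -> Path:
    """Write labels as 8-bit multi-page TIFF; class map goes in the sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.labels.astype(np.uint8))
    meta = {
        "voxel_size_um": float(labels.voxel_size_um),
        "shape": [int(n) for n in labels.shape],
        "class_map": {int(k): v for k, v in labels.class_map.items()},
    }
    with sidecar_path(path).open("w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_labels(path: Path | str, voxel_size_um: float | None = None) -> LabelVolume:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = _read_sidecar(path)
    vs = voxel_size_um if voxel_size_um is not None else meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(f"voxel size unknown for {path}")
    class_map = {int(k): v for k, v in meta.get("class_map", CLASS_NAMES).items()}
    return LabelVolume(data, float(vs), class_map)
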