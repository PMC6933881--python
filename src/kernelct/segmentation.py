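"""Grayscale kernel volume -> semantic label volume.

The processing chain mirrors standard micro-CT practice for single-seed
scans: median denoise, global class thresholds (multi-class Otsu by
default, or fixed midpoints when the class grey levels are known),
region-growing refinement of the endosperm/embryo split from
high-confidence cores, small-object cleanup by majority reassignment, and
positional classification of cavities into subcutaneous / endosperm /
embryo classes. The seed coat is recovered geometrically as the outer
shell of the kernel (its attenuation is indistinguishable from endosperm
at 8 bits), with configurable thickness.

Connectivity follows the standard duality: 26-connectivity for foreground
objects, 6-connectivity for background and cavities, which prevents
background "tunnels" leaking through voxel corners into interior voids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volume import (
    BACKGROUND,
    CAVITY_CLASSES,
    CAVITY_EMBRYO,
    CAVITY_ENDOSPERM,
    CAVITY_GENERIC,
    CAVITY_SUBCUTANEOUS,
    CLASS_NAMES,
    EMBRYO,
    ENDOSPERM,
    SEED_COAT,
    STRUCT_6,
    STRUCT_26,
    LabelVolume,
    VoxelVolume,
    ball,
    dilate,
    erode,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "KernelSegmenter",
    "denoise",
    "segment_components",
    "clean_labels",
    "classify_cavities",
    "evaluate_segmentation",
]


@dataclass
class SegmentationConfig:
    """Tunable knobs of the segmentation chain.

    ``grey_levels`` switches thresholding from multi-Otsu to fixed
    midpoints between the known class means (phantom/test mode).
    ``subcutaneous_margin_vox`` is the distance from the kernel outer
    surface within which a cavity counts as subcutaneous.
    """

    denoise_radius_vox: int = 1
    threshold_method: str = "multiotsu"  # or "midpoint" (needs grey_levels)
    grey_levels: dict[str, float] | None = None
    coat_thickness_mm: float = 0.14
    region_growing_tolerance: float = 40.0
    cleanup_radius_vox: int = 1
    min_object_vox: int = 27
    subcutaneous_margin_vox: int = 2
    max_foreground_components: int = 1

    def validate(self) -> None:
        if self.denoise_radius_vox < 0 or self.cleanup_radius_vox < 0:
            raise ValueError("radii must be >= 0")
        if self.min_object_vox < 1:
            raise ValueError("min_object_vox must be >= 1")
        if self.threshold_method not in ("multiotsu", "midpoint"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "midpoint" and not self.grey_levels:
            raise ValueError("midpoint thresholding needs grey_levels")


def denoise(volume: VoxelVolume, config: SegmentationConfig) -> VoxelVolume:
    """Median-filter the volume; radius 0 is the identity.

    The median preserves edges and the intensity range (every output value
    is an order statistic of input values), which is what matters before
    histogram thresholding.
    """
    r = config.denoise_radius_vox
    if r < 0:
        raise ValueError("denoise radius must be >= 0")
    if r == 0:
        return volume.with_data(volume.data.copy(), "denoise(identity)")
    filtered = ndimage.median_filter(volume.data, footprint=ball(r))
    return volume.with_data(filtered, f"median(r={r})")


def _class_thresholds(data: np.ndarray, config: SegmentationConfig) -> tuple[float, float, float]:
    """(background|cavity, cavity|endosperm, endosperm|embryo) thresholds."""
    if config.threshold_method == "midpoint":
        g = config.grey_levels
        return (
            (g["background"] + g["cavity"]) / 2.0,
            (g["cavity"] + min(g["endosperm"], g["seed_coat"])) / 2.0,
            (max(g["endosperm"], g["seed_coat"]) + g["embryo"]) / 2.0,
        )
    # Otsu over 4 intensity classes: background, cavity, endosperm(+coat), embryo
    t = threshold_multiotsu(data, classes=4)
    return tuple(float(x) for x in t)


def _region_grow(
    data: np.ndarray,
    material: np.ndarray,
    t_embryo: float,
    tolerance: float,
) -> np.ndarray:
    """Split material voxels into endosperm vs embryo by seeded growth.

    Seeds are the eroded high-confidence cores of each side of the
    endosperm/embryo threshold; each unassigned material voxel is then
    claimed, in alternating one-voxel dilation rounds, by the class whose
    running mean grey value it is within ``tolerance`` of. Leftover voxels
    (none, for well-separated classes) fall back to the nearer class mean.
    """
    embryo0 = material & (data >= t_embryo)
    endo0 = material & (data < t_embryo)
    embryo = erode(embryo0, 1)
    endo = erode(endo0, 1)
    if not embryo.any():
        embryo = embryo0
    if not endo.any():
        endo = endo0
    unassigned = material & ~embryo & ~endo
    means = {}
    for _ in range(512):
        if not unassigned.any():
            break
        progressed = False
        for cls_mask in (endo, embryo):
            if not cls_mask.any():
                continue
            mean = float(data[cls_mask].mean())
            frontier = ndimage.binary_dilation(cls_mask, STRUCT_26) & unassigned
            take = frontier & (np.abs(data.astype(np.float32) - mean) <= tolerance)
            if take.any():
                cls_mask |= take
                unassigned &= ~take
                progressed = True
        if not progressed:
            break
    if unassigned.any():
        # fall back: nearer class mean
        em_mean = float(data[embryo].mean()) if embryo.any() else np.inf
        en_mean = float(data[endo].mean()) if endo.any() else np.inf
        d_em = np.abs(data.astype(np.float32) - em_mean)
        d_en = np.abs(data.astype(np.float32) - en_mean)
        embryo |= unassigned & (d_em < d_en)
        endo |= unassigned & (d_em >= d_en)
    return embryo


def segment_components(
    volume: VoxelVolume, config: SegmentationConfig | None = None
) -> LabelVolume:
    """Threshold + region-grow one kernel into labelled components.

    Cavities come out with the transient generic cavity code; run
    :func:`classify_cavities` (or use :class:`KernelSegmenter`) to assign
    the three location classes. Raises if no foreground is found or if more
    than one large foreground object is present (one kernel per volume).
    """
    config = config or SegmentationConfig()
    config.validate()
    data = volume.data
    t_bg, t_mat, t_em = _class_thresholds(data, config)

    material = data >= t_mat
    if not material.any():
        raise ValueError("no foreground found above the material threshold")
    comp, n = ndimage.label(material, structure=STRUCT_26)
    sizes = np.bincount(comp.ravel())[1:]
    big = np.flatnonzero(sizes >= config.min_object_vox) + 1
    if len(big) == 0:
        raise ValueError("no foreground found (all objects below minimum size)")
    if len(big) > config.max_foreground_components:
        raise ValueError(
            "more than one large foreground component: sizes "
            f"{sorted(sizes[big - 1].tolist(), reverse=True)}"
        )
    keep = max(big, key=lambda i: sizes[i - 1])
    material = comp == keep

    # interior voids: fill with 6-connected background so corner-diagonal
    # leaks cannot open a cavity to the outside
    grain = ndimage.binary_fill_holes(material, structure=STRUCT_6)
    cavity = grain & ~material

    embryo = _region_grow(data, material, t_em, config.region_growing_tolerance)

    labels = np.zeros(volume.shape, dtype=np.uint8)
    k_coat = int(round(config.coat_thickness_mm / volume.voxel_size_mm))
    shell = grain & ~erode(grain, k_coat) if k_coat > 0 else np.zeros_like(grain)
    labels[material] = ENDOSPERM
    labels[shell & material & ~embryo] = SEED_COAT
    labels[embryo] = EMBRYO
    labels[cavity] = CAVITY_GENERIC

    logger.info(
        "segment: material=%d cavity=%d embryo=%d coat=%d",
        int(material.sum()), int(cavity.sum()), int(embryo.sum()),
        int((labels == SEED_COAT).sum()),
    )
    return LabelVolume(labels, volume.voxel_size_um, dict(CLASS_NAMES))


def clean_labels(
    labels: LabelVolume, config: SegmentationConfig | None = None
) -> LabelVolume:
    """Reassign objects smaller than the minimum size to their surroundings.

    For every class, connected components (26-conn) below
    ``min_object_vox`` take the majority label of their one-voxel border.
    Foreground voxels never become background (label conservation), so the
    operation only re-classes voxels; it is idempotent on clean input.
    """
    config = config or SegmentationConfig()
    config.validate()
    out = labels.labels.copy()
    for cls in np.unique(out):
        if cls == BACKGROUND:
            continue
        mask = out == cls
        comp, n = ndimage.label(mask, structure=STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        for i in range(1, n + 1):
            if sizes[i] >= config.min_object_vox:
                continue
            obj = comp == i
            border = ndimage.binary_dilation(obj, STRUCT_26) & ~obj
            neigh = out[border]
            neigh = neigh[neigh != BACKGROUND]  # conserve foreground
            if neigh.size == 0:
                continue
            out[obj] = np.bincount(neigh).argmax()
    return LabelVolume(out, labels.voxel_size_um, dict(labels.class_map))


def classify_cavities(
    labels: LabelVolume, config: SegmentationConfig | None = None
) -> LabelVolume:
    """Assign every generic-cavity component a location class.

    Per 26-connected cavity component, in order:

    1. embryo cavity, if its one-voxel dilation shell overlaps embryo more
       than any other class;
    2. subcutaneous, if the shell touches the seed-coat shell or the
       component lies within ``subcutaneous_margin_vox`` (plus the coat
       thickness) of the kernel outer surface;
    3. endosperm cavity otherwise.

    Components are never split. A component whose shell touches background
    (an open pore) triggers a warning and falls through the same rules.
    Volumes without generic cavity voxels are returned unchanged.
    """
    config = config or SegmentationConfig()
    out = labels.labels.copy()
    generic = out == CAVITY_GENERIC
    if not generic.any():
        return LabelVolume(out, labels.voxel_size_um, dict(labels.class_map))

    grain = out != BACKGROUND
    # distance (in voxels) of every grain voxel to the outer surface
    depth = ndimage.distance_transform_edt(grain)
    k_coat = int(round(config.coat_thickness_mm / labels.voxel_size_mm))
    near_surface = depth <= k_coat + config.subcutaneous_margin_vox

    comp, n = ndimage.label(generic, structure=STRUCT_26)
    for i in range(1, n + 1):
        obj = comp == i
        shell = ndimage.binary_dilation(obj, STRUCT_26) & ~obj
        shell_labels = out[shell]
        if (shell_labels == BACKGROUND).any():
            warnings.warn(
                f"cavity component {i} touches background (open pore); "
                "classifying by its shell anyway",
                stacklevel=2,
            )
        n_embryo = int((shell_labels == EMBRYO).sum())
        n_coat = int((shell_labels == SEED_COAT).sum())
        n_endo = int((shell_labels == ENDOSPERM).sum())
        if n_embryo > max(n_coat, n_endo):
            cls = CAVITY_EMBRYO
        elif n_coat > 0 or bool((near_surface & obj).any()):
            cls = CAVITY_SUBCUTANEOUS
        else:
            cls = CAVITY_ENDOSPERM
        out[obj] = cls
    return LabelVolume(out, labels.voxel_size_um, dict(labels.class_map))


def evaluate_segmentation(
    pred: LabelVolume, truth: LabelVolume
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-class Dice coefficients and the full confusion table.

    Dice(class) = 2|P & T| / (|P| + |T|); classes absent from both volumes
    are omitted. The confusion table is truth rows x prediction columns,
    counts summing to the total voxel count.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.labels.ravel()
    t = truth.labels.ravel()
    k = max(int(p.max()), int(t.max())) + 1
    conf = np.bincount(t.astype(np.int64) * k + p, minlength=k * k).reshape(k, k)
    names = [CLASS_NAMES.get(i, str(i)) for i in range(k)]
    table = pd.DataFrame(conf, index=pd.Index(names, name="truth"),
                         columns=pd.Index(names, name="pred"))
    dice: dict[str, float] = {}
    for i in range(k):
        n_p, n_t = conf[:, i].sum(), conf[i, :].sum()
        if n_p == 0 and n_t == 0:
            continue
        dice[names[i]] = 2.0 * conf[i, i] / (n_p + n_t)
    return dice, table


class KernelSegmenter:
    """The full chain as one configurable object.

    ``segment(volume)`` runs denoise -> threshold/region-grow -> cleanup ->
    cavity classification and returns a :class:`LabelVolume`. Parameters
    mirror :class:`SegmentationConfig`; ``get_params``/``set_params`` follow
    the sklearn convention so the object drops into grid searches over
    segmentation settings.
    """

    def __init__(self, **config_kwargs):
        self.config = SegmentationConfig(**config_kwargs)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self.config, k) for k in vars(self.config)}

    def set_params(self, **params) -> "KernelSegmenter":
        for k, v in params.items():
            if not hasattr(self.config, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self.config, k, v)
        return self

    def segment(self, volume: VoxelVolume) -> LabelVolume:
        cfg = self.config
        cfg.validate()
        den = denoise(volume, cfg)
        labels = segment_components(den, cfg)
        labels = clean_labels(labels, cfg)
        return classify_cavities(labels, cfg)

    __call__ = segment
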