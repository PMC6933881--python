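"""Synthetic maize-kernel phantoms with exact ground truth.

No public micro-CT scan of a maize kernel ships with this package, so every
downstream stage (segmentation, morphometry, statistics) is validated
against voxel phantoms generated here. A phantom is a kernel-shaped
superellipsoid with a uniform seed-coat shell, a half-ellipsoid embryo lobe
flush with one broad face, and spherical air cavities planted in the three
location classes the field distinguishes: subcutaneous (touching the
coat-endosperm interface), endosperm (strictly interior) and embryo
(inside the germ). Class-mean grey levels follow the brightness ordering of
real kernel scans — background < cavity < endosperm ~ seed coat < embryo —
and additive Gaussian noise emulates detector noise.

A companion cohort simulator draws per-kernel structural parameters and a
breakage outcome that is linear in subcutaneous cavity volume and grain
density, so estimator-recovery experiments have a known generating model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import morphometry
from .volume import (
    BACKGROUND,
    CAVITY_EMBRYO,
    CAVITY_ENDOSPERM,
    CAVITY_SUBCUTANEOUS,
    CLASS_NAMES,
    EMBRYO,
    ENDOSPERM,
    SEED_COAT,
    LabelVolume,
    VoxelVolume,
    erode,
)

__all__ = [
    "CavityClassSpec",
    "KernelPhantomSpec",
    "PhantomTruth",
    "CohortDesign",
    "generate_kernel_phantom",
    "simulate_cohort_table",
    "generate_cohort",
    "coat_radius_vox",
]


def coat_radius_vox(coat_thickness_mm: float, voxel_size_mm: float) -> int:
    """Seed-coat shell thickness in whole voxels (shared with segmentation)."""
    return int(round(coat_thickness_mm / voxel_size_mm))


@dataclass
class CavityClassSpec:
    """How many cavities of one location class to plant, and how large.

    ``radius_range_mm`` is sampled uniformly per cavity. Placement rules are
    fixed by the location class, not configurable: subcutaneous cavities are
    seated against the coat-endosperm interface, endosperm cavities keep a
    clearance from both coat and embryo, embryo cavities sit inside the lobe.
    """

    count: int = 0
    radius_range_mm: tuple[float, float] = (0.2, 0.4)

    def validate(self, name: str) -> None:
        if self.count < 0:
            raise ValueError(f"{name}: cavity count must be >= 0")
        lo, hi = self.radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError(f"{name}: invalid radius range {self.radius_range_mm}")


def _default_cavities() -> dict[str, CavityClassSpec]:
    # Sized so per-class cavity volumes land in the low-mm^3 range typical
    # of air-dried dent kernels (subcutaneous ~1-6 mm^3, endosperm ~3-8,
    # embryo ~1.5-4).
    return {
        "subcutaneous": CavityClassSpec(4, (0.5, 0.75)),
        "endosperm": CavityClassSpec(3, (0.65, 0.9)),
        "embryo": CavityClassSpec(2, (0.4, 0.55)),
    }


def _default_grey_levels() -> dict[str, float]:
    # Seed coat defaults to the endosperm level: attenuation of pericarp and
    # starchy endosperm is near-indistinguishable at 8 bits, so the coat is
    # recovered geometrically rather than radiometrically.
    return {
        "background": 10.0,
        "cavity": 40.0,
        "seed_coat": 120.0,
        "endosperm": 120.0,
        "embryo": 200.0,
    }


@dataclass
class KernelPhantomSpec:
    """Full description of one synthetic kernel volume.

    Parameters
    ----------
    body_semi_axes_mm : (a, b, c)
        Outer half-lengths along length, width, thickness. Defaults give a
        14 x 8.4 x 4.5 mm kernel, the size range of dent maize.
    shape_exponent : float
        Superellipsoid exponent; 2 is an ellipsoid, the default 2.5 gives
        the flattened-ovoid silhouette of a real kernel.
    coat_thickness_mm : float
        Uniform pericarp shell obtained by morphological erosion.
    embryo_fraction : float
        Target embryo : grain volume ratio (real kernels: 0.08-0.11).
    embryo_placement : float
        Offset of the embryo lobe centre along the length axis, as a
        fraction of the length semi-axis.
    grid_shape : optional
        Voxels per axis. ``None`` derives the tightest grid that leaves
        ``margin_vox`` background voxels on every face.
    grey_levels : mapping class name -> mean 8-bit intensity
        Must respect background < cavity < endosperm <= embryo brightness
        ordering (embryo is the brightest tissue in kernel CT).
    noise_sd : float
        Additive Gaussian noise, 8-bit grey values; clipped to [0, 255].
    mass_density_g_cm3 : float
        Apparent kernel density (cavity-inclusive) used to derive the mass.
    """

    body_semi_axes_mm: tuple[float, float, float] = (7.0, 4.2, 2.25)
    voxel_size_um: float = 70.0
    shape_exponent: float = 2.5
    coat_thickness_mm: float = 0.14
    embryo_fraction: float = 0.10
    embryo_placement: float = 0.12
    grid_shape: tuple[int, int, int] | None = None
    margin_vox: int = 4
    cavity_spec: dict[str, CavityClassSpec] = field(default_factory=_default_cavities)
    grey_levels: dict[str, float] = field(default_factory=_default_grey_levels)
    noise_sd: float = 8.0
    mass_density_g_cm3: float = 1.20
    rng_seed: int = 0

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def validate(self) -> None:
        a, b, c = self.body_semi_axes_mm
        if min(a, b, c) <= 0 or self.voxel_size_um <= 0 or self.coat_thickness_mm < 0:
            raise ValueError("geometric lengths must be positive")
        if not 0 <= self.embryo_fraction < 0.5:
            raise ValueError("embryo_fraction must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mass_density_g_cm3 <= 0:
            raise ValueError("mass_density must be > 0")
        g = self.grey_levels
        required = {"background", "cavity", "seed_coat", "endosperm", "embryo"}
        if set(g) != required:
            raise ValueError(f"grey_levels must define exactly {sorted(required)}")
        if not (g["background"] < g["cavity"] < g["endosperm"] <= g["embryo"]):
            raise ValueError(
                "grey levels must satisfy background < cavity < endosperm <= embryo"
            )
        if g["embryo"] <= g["endosperm"] or g["embryo"] <= g["seed_coat"]:
            raise ValueError("embryo must be the brightest non-background class")
        for name, cs in self.cavity_spec.items():
            cs.validate(name)
            if cs.radius_range_mm[1] >= min(a, b, c):
                raise ValueError(f"{name}: cavity radius does not fit inside the body")
        shape = self.resolved_grid_shape()
        half_extent_vox = np.array([a, b, c]) / self.voxel_size_mm
        if np.any(np.asarray(shape) < 2 * half_extent_vox + 2 * self.margin_vox):
            raise ValueError(
                f"grid {shape} does not enclose the body with a "
                f"{self.margin_vox}-voxel margin"
            )

    def resolved_grid_shape(self) -> tuple[int, int, int]:
        if self.grid_shape is not None:
            return tuple(int(n) for n in self.grid_shape)
        half = np.asarray(self.body_semi_axes_mm) / self.voxel_size_mm
        return tuple(int(np.ceil(2 * h)) + 2 * self.margin_vox for h in half)


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    label_volume: LabelVolume
    true_parameters: "morphometry.KernelMorphometry"
    mass_mg: float


def _superellipsoid_mask(
    shape: tuple[int, int, int], semi_axes_mm, voxel_mm: float, exponent: float
) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * voxel_mm for n in shape
    ]
    zz = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    xx = coords[2][None, None, :]
    a, b, c = semi_axes_mm
    p = exponent
    return (
        np.abs(zz / a) ** p + np.abs(yy / b) ** p + np.abs(xx / c) ** p
    ) <= 1.0


def _carve_sphere(target: np.ndarray, center_vox, radius_vox: float) -> np.ndarray:
    """Boolean ball of (float) voxel radius around an integer center."""
    r = int(np.ceil(radius_vox))
    lo = [max(0, int(c) - r) for c in center_vox]
    hi = [min(n, int(c) + r + 1) for c, n in zip(center_vox, target.shape)]
    out = np.zeros_like(target, dtype=bool)
    sub = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = sum((sub[i] - center_vox[i]) ** 2 for i in range(3))
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= radius_vox**2
    return out


def _place_cavities(
    labels: np.ndarray,
    spec: KernelPhantomSpec,
    rng: np.random.Generator,
) -> None:
    """Plant spherical cavities per location class, in place.

    Subcutaneous cavities are centred one radius inside the coat-endosperm
    interface so they touch it; endosperm cavities keep >= 3 voxels of
    clearance from anything that is not endosperm; embryo cavities fit
    wholly inside the lobe. Overlap between cavities is rejected so each
    cavity stays one connected component of its own class.
    """
    vox = spec.voxel_size_mm
    max_tries = 200
    class_code = {
        "subcutaneous": CAVITY_SUBCUTANEOUS,
        "endosperm": CAVITY_ENDOSPERM,
        "embryo": CAVITY_EMBRYO,
    }
    for name in ("embryo", "subcutaneous", "endosperm"):
        cspec = spec.cavity_spec.get(name)
        if cspec is None or cspec.count == 0:
            continue
        for i in range(cspec.count):
            placed = False
            for _ in range(max_tries):
                r_mm = rng.uniform(*cspec.radius_range_mm)
                r_vox = r_mm / vox
                if name == "embryo":
                    host = labels == EMBRYO
                    dist = ndimage.distance_transform_edt(host)
                    ok = dist > r_vox + 1
                elif name == "endosperm":
                    host = labels == ENDOSPERM
                    dist = ndimage.distance_transform_edt(host)
                    ok = dist > r_vox + 3
                else:  # subcutaneous: touch the coat interface
                    interior = (labels == ENDOSPERM) | (labels == EMBRYO)
                    dist = ndimage.distance_transform_edt(interior)
                    near = np.abs(dist - r_vox) <= 1.0
                    ok = near & (labels == ENDOSPERM)
                if not ok.any():
                    continue
                idx = rng.integers(ok.sum())
                center = np.argwhere(ok)[idx]
                ball_mask = _carve_sphere(labels, center, r_vox)
                if name == "subcutaneous":
                    ball_mask &= labels == ENDOSPERM
                region = labels[ball_mask]
                host_code = EMBRYO if name == "embryo" else ENDOSPERM
                if region.size == 0 or not np.all(region == host_code):
                    continue
                labels[ball_mask] = class_code[name]
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place {name} cavity #{i + 1} after {max_tries} tries"
                )


def generate_kernel_phantom(
    spec: KernelPhantomSpec,
) -> tuple[VoxelVolume, PhantomTruth]:
    """Render one grayscale kernel volume plus its ground truth.

    Returns the 8-bit grayscale volume and a :class:`PhantomTruth` whose
    labels, morphometric parameters and mass are exactly consistent with
    the rendered geometry. The same spec and seed always reproduce the
    same volumes bit for bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.resolved_grid_shape()
    vox = spec.voxel_size_mm

    body = _superellipsoid_mask(
        shape, spec.body_semi_axes_mm, vox, spec.shape_exponent
    )
    if not body.any():
        raise ValueError("body mask is empty; check semi-axes vs voxel size")
    # margin check on the rendered mask (validate() checked the analytic bound)
    for ax in range(3):
        proj = body.any(axis=tuple(i for i in range(3) if i != ax))
        first, last = np.argmax(proj), len(proj) - 1 - np.argmax(proj[::-1])
        if first < 2 or last > len(proj) - 3:
            raise ValueError("body exceeds grid: < 2 voxels of background margin")

    labels = np.zeros(shape, dtype=np.uint8)
    k_coat = coat_radius_vox(spec.coat_thickness_mm, vox)
    interior = erode(body, k_coat)
    labels[body] = SEED_COAT
    labels[interior] = ENDOSPERM

    if spec.embryo_fraction > 0:
        labels = _add_embryo(labels, interior, spec, body_volume_vox=body.sum())

    _place_cavities(labels, spec, rng)

    grey_of = {
        BACKGROUND: spec.grey_levels["background"],
        SEED_COAT: spec.grey_levels["seed_coat"],
        ENDOSPERM: spec.grey_levels["endosperm"],
        EMBRYO: spec.grey_levels["embryo"],
        CAVITY_SUBCUTANEOUS: spec.grey_levels["cavity"],
        CAVITY_ENDOSPERM: spec.grey_levels["cavity"],
        CAVITY_EMBRYO: spec.grey_levels["cavity"],
    }
    lut = np.zeros(8, dtype=np.float64)
    for code, g in grey_of.items():
        lut[code] = g
    grey = lut[labels]
    if spec.noise_sd > 0:
        grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)
    grey = np.clip(np.rint(grey), 0, 255).astype(np.uint8)

    label_volume = LabelVolume(labels, spec.voxel_size_um, dict(CLASS_NAMES))
    grain_volume_mm3 = float(body.sum()) * vox**3
    mass_mg = spec.mass_density_g_cm3 * grain_volume_mm3  # g/cm^3 == mg/mm^3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = morphometry.compute_all_parameters(label_volume, mass_mg)
    truth = PhantomTruth(label_volume, params, mass_mg)
    volume = VoxelVolume(
        grey, spec.voxel_size_um, provenance=f"phantom(seed={spec.rng_seed})"
    )
    return volume, truth


def _add_embryo(
    labels: np.ndarray,
    interior: np.ndarray,
    spec: KernelPhantomSpec,
    body_volume_vox: int,
) -> np.ndarray:
    """Carve a half-ellipsoid embryo lobe flush with one broad face."""
    shape = labels.shape
    vox = spec.voxel_size_mm
    a, b, c = spec.body_semi_axes_mm
    coords = [(np.arange(n) - (n - 1) / 2.0) * vox for n in shape]
    zz = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    xx = coords[2][None, None, :]

    # proportions of the lobe relative to the kernel; overall scale s solves
    # (2/3)*pi*ae*be*ce = embryo_fraction * body volume
    alpha, beta, gamma = 0.55, 0.55, 0.80
    target_mm3 = spec.embryo_fraction * body_volume_vox * vox**3
    s = (target_mm3 / ((2 / 3) * np.pi * alpha * a * beta * b * gamma * c)) ** (1 / 3)
    ae, be, ce = alpha * a * s, beta * b * s, gamma * c * s

    x0 = -(c - spec.coat_thickness_mm - vox)  # base plane just inside the coat
    z0 = spec.embryo_placement * a
    ell = (
        ((zz - z0) / ae) ** 2 + (yy / be) ** 2 + ((xx - x0) / ce) ** 2
    ) <= 1.0
    lobe = ell & (xx >= x0) & interior
    labels[lobe] = EMBRYO
    return labels


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortDesign:
    """Design of a simulated variety cohort with a known breakage model.

    Breakage rate (a mass fraction in [0, 1]) is generated as

        BR = b0 + b_vsc * Vsc + b_de * DE + eps,  eps ~ N(0, noise_sd)

    i.e. linear in subcutaneous cavity volume (mm^3) and apparent density
    (g/cm^3), the two structural drivers of mechanical breakage. Default
    coefficients (1.381, 0.010, -0.724) and parameter ranges match the
    magnitudes observed in air-dried dent maize cohorts; nuisance columns
    are drawn independently of breakage so selection procedures can be
    scored against a known active set.
    """

    n_varieties: int = 6
    replicates_per_variety: int = 3
    vsc_range_mm3: tuple[float, float] = (1.3, 5.9)
    density_range_g_cm3: tuple[float, float] = (1.14, 1.28)
    nuisance_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"SSAg": (1.30, 1.46), "SP": (0.507, 0.565)}
    )
    breakage_model: tuple[float, float, float] = (1.381, 0.010, -0.724)
    noise_sd: float = 0.005
    replicate_jitter: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_varieties < 2:
            raise ValueError("a cohort needs at least 2 varieties")
        if self.replicates_per_variety < 1:
            raise ValueError("replicates_per_variety must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in {
            "vsc_range_mm3": self.vsc_range_mm3,
            "density_range_g_cm3": self.density_range_g_cm3,
            **self.nuisance_ranges,
        }.items():
            if not lo <= hi:
                raise ValueError(f"{name}: empty range ({lo}, {hi})")


def simulate_cohort_table(design: CohortDesign) -> pd.DataFrame:
    """Simulate the per-kernel parameter table without rendering volumes.

    Variety-level parameter means are drawn uniformly from the design
    ranges; replicates scatter around them with relative jitter
    ``replicate_jitter``. Breakage values falling outside (0, 1) are never
    clipped: they are kept as-is and flagged in the ``br_out_of_range``
    column (with a warning), so a mis-specified design is visible.
    """
    design.validate()
    rng = np.random.default_rng(design.rng_seed)
    b0, b_vsc, b_de = design.breakage_model

    rows = []
    for v in range(design.n_varieties):
        means = {
            "Vsc": rng.uniform(*design.vsc_range_mm3),
            "DE": rng.uniform(*design.density_range_g_cm3),
        }
        for name, rng_pair in design.nuisance_ranges.items():
            means[name] = rng.uniform(*rng_pair)
        for r in range(design.replicates_per_variety):
            row = {"variety": f"V{v + 1:02d}", "replicate": r + 1}
            for name, mu in means.items():
                jitter = design.replicate_jitter * abs(mu)
                row[name] = mu + rng.normal(0.0, jitter) if jitter > 0 else mu
            eps = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
            row["BR"] = b0 + b_vsc * row["Vsc"] + b_de * row["DE"] + eps
            rows.append(row)
    table = pd.DataFrame(rows)
    out_of_range = (table["BR"] <= 0) | (table["BR"] >= 1)
    table["br_out_of_range"] = out_of_range
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} simulated breakage values fall outside "
            "(0, 1); flagged in 'br_out_of_range', not clipped",
            stacklevel=2,
        )
    return table


def generate_cohort(
    design: CohortDesign,
    phantom_template: KernelPhantomSpec | None = None,
    render_volumes: bool = True,
) -> tuple[list[tuple[VoxelVolume, PhantomTruth]], pd.DataFrame]:
    """Render one phantom per kernel and build the cohort table.

    When volumes are rendered, the table's structural columns are the
    *measured* truth of each rendered phantom (its actual subcutaneous
    cavity volume and density), and breakage is computed from those values,
    so the generating model holds exactly for the data a user will analyse.
    With ``render_volumes=False`` this reduces to
    :func:`simulate_cohort_table` and returns an empty phantom list.
    """
    design.validate()
    if not render_volumes:
        return [], simulate_cohort_table(design)

    template = phantom_template or KernelPhantomSpec()
    rng = np.random.default_rng(design.rng_seed)
    b0, b_vsc, b_de = design.breakage_model
    phantoms: list[tuple[VoxelVolume, PhantomTruth]] = []
    rows = []
    for v in range(design.n_varieties):
        vsc_target = rng.uniform(*design.vsc_range_mm3)
        density = rng.uniform(*design.density_range_g_cm3)
        for r in range(design.replicates_per_variety):
            spec = _spec_for_kernel(
                template, vsc_target, density, seed=int(rng.integers(2**31))
            )
            vol, truth = generate_kernel_phantom(spec)
            p = truth.true_parameters
            eps = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
            br = b0 + b_vsc * p.Vsc + b_de * p.DE + eps
            row = {"variety": f"V{v + 1:02d}", "replicate": r + 1}
            row.update(p.as_dict())
            row["BR"] = br
            rows.append(row)
            phantoms.append((vol, truth))
    table = pd.DataFrame(rows)
    out_of_range = (table["BR"] <= 0) | (table["BR"] >= 1)
    table["br_out_of_range"] = out_of_range
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} simulated breakage values fall outside "
            "(0, 1); flagged, not clipped",
            stacklevel=2,
        )
    return phantoms, table


def _spec_for_kernel(
    template: KernelPhantomSpec,
    vsc_target_mm3: float,
    density: float,
    seed: int,
) -> KernelPhantomSpec:
    """Derive a per-kernel spec whose subcutaneous cavities approximate a target volume."""
    cav = {k: CavityClassSpec(v.count, v.radius_range_mm) for k, v in template.cavity_spec.items()}
    n_sc = max(cav.get("subcutaneous", CavityClassSpec(2)).count, 1)
    # interface-seated spheres lose roughly a third of their volume to clipping
    r = (vsc_target_mm3 / n_sc * 3 / (4 * np.pi) * 1.5) ** (1 / 3)
    cav["subcutaneous"] = CavityClassSpec(n_sc, (0.9 * r, 1.1 * r))
    return KernelPhantomSpec(
        body_semi_axes_mm=template.body_semi_axes_mm,
        voxel_size_um=template.voxel_size_um,
        shape_exponent=template.shape_exponent,
        coat_thickness_mm=template.coat_thickness_mm,
        embryo_fraction=template.embryo_fraction,
        embryo_placement=template.embryo_placement,
        grid_shape=template.grid_shape,
        margin_vox=template.margin_vox,
        cavity_spec=cav,
        grey_levels=dict(template.grey_levels),
        noise_sd=template.noise_sd,
        mass_density_g_cm3=density,
        rng_seed=seed,
    )
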