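"""Synthetic pelvic CT phantoms with organ label masks.

The generator emulates a planning-CT cohort for localised prostate cancer:
an elliptic soft-tissue body cylinder containing pelvic bone structures
(femoral heads, iliac rods), a bladder anterior-superior to the prostate,
and a rectum posterior to it, optionally carrying an air pocket.  Geometry
is parametric (ellipsoids / cylinders in world millimetres), which is all
the downstream dose-sensitivity analysis needs: relative organ position,
size, and Hounsfield-unit contrast.

World coordinates follow the LPS convention (x: left, y: posterior,
z: superior); the grid centre sits at the world origin by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

__all__ = [
    "CTVolume",
    "OrganMaskSet",
    "PhantomSpec",
    "PhantomGeometryError",
    "generate_phantom",
    "jitter_spec",
    "cohort",
    "mask_centroid",
]

HU_MIN = -1024.0
HU_MAX = 3100.0

STRUCTURES = ("body", "bone", "bladder", "rectum", "prostate")


class PhantomGeometryError(ValueError):
    """Raised when a spec places organs outside the body or overlapping."""


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT image: Hounsfield units on a regular grid.

    ``voxels`` is indexed ``[i, j, k]`` along world axes (x, y, z); the world
    position of voxel (i, j, k) is ``origin + (i, j, k) * spacing`` (mm).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the voxel-centre hull, mm."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        return tuple(lo[a] + np.arange(self.shape[a]) * sp[a] for a in range(3))


@dataclass(frozen=True)
class OrganMaskSet:
    """Boolean masks on the CT grid for the five delineated structures.

    Bone, bladder, rectum and prostate are pairwise disjoint subsets of the
    body; "remaining soft tissue" is body minus the four organs.
    """

    body: np.ndarray
    bone: np.ndarray
    bladder: np.ndarray
    rectum: np.ndarray
    prostate: np.ndarray

    def __post_init__(self) -> None:
        shape = self.body.shape
        for name in STRUCTURES:
            m = getattr(self, name)
            if m.dtype != bool:
                raise ValueError(f"mask '{name}' must be boolean")
            if m.shape != shape:
                raise ValueError(f"mask '{name}' shape {m.shape} != body shape {shape}")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in STRUCTURES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return ((name, getattr(self, name)) for name in STRUCTURES)

    def remaining_soft_tissue(self) -> np.ndarray:
        """Body minus bone, bladder, rectum and prostate."""
        organs = self.bone | self.bladder | self.rectum | self.prostate
        return self.body & ~organs

    def validate(self) -> None:
        """Check disjointness / containment invariants, raising on violation."""
        organ_names = ("bone", "bladder", "rectum", "prostate")
        for i, a in enumerate(organ_names):
            if not np.all(self.body[getattr(self, a)]):
                raise PhantomGeometryError(f"structure '{a}' extends outside the body")
            for b in organ_names[i + 1:]:
                if np.any(getattr(self, a) & getattr(self, b)):
                    raise PhantomGeometryError(f"structures '{a}' and '{b}' overlap")
        if not self.prostate.any():
            raise PhantomGeometryError("prostate mask is empty")
        if not self.remaining_soft_tissue().any():
            raise PhantomGeometryError("no remaining soft tissue left in body")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic patient.

    Geometry is expressed in world mm around the grid centre.  Tissue HU are
    (mean, sd) pairs; voxel noise is Gaussian, truncated at 3.5 sd so every
    tissue's histogram stays inside its nominal band.
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)

    # body: elliptic cylinder along z, (x, y) semi-axes in mm
    body_radii_mm: tuple[float, float] = (115.0, 90.0)

    prostate_centre_mm: tuple[float, float, float] = (0.0, 10.0, 0.0)
    prostate_radii_mm: tuple[float, float, float] = (17.0, 13.0, 14.0)

    bladder_centre_mm: tuple[float, float, float] = (0.0, -35.0, 20.0)
    bladder_radii_mm: tuple[float, float, float] = (30.0, 22.0, 24.0)

    # rectum: cylinder along z
    rectum_centre_mm: tuple[float, float] = (0.0, 46.0)
    rectum_radius_mm: float = 18.0
    rectum_half_length_mm: float = 55.0

    # bone: two femoral-head spheres plus two iliac rods (cylinders along z)
    femoral_centre_mm: tuple[float, float, float] = (82.0, 20.0, 0.0)
    femoral_radius_mm: float = 21.0
    iliac_centre_mm: tuple[float, float] = (62.0, 52.0)
    iliac_radius_mm: float = 11.0
    iliac_half_length_mm: float = 40.0

    # (mean, sd) Hounsfield units per tissue class
    soft_tissue_hu: tuple[float, float] = (40.0, 10.0)
    bone_hu: tuple[float, float] = (600.0, 150.0)
    bladder_hu: tuple[float, float] = (10.0, 8.0)
    prostate_hu: tuple[float, float] = (40.0, 8.0)
    rectum_hu: tuple[float, float] = (-20.0, 15.0)

    rectal_gas_probability: float = 0.3
    gas_radius_mm: float = 7.0
    gas_hu: float = -1000.0
    outside_hu: float = -1000.0

    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise ValueError("grid too small for a pelvic phantom")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not (0.0 <= self.rectal_gas_probability <= 1.0):
            raise ValueError("rectal_gas_probability must lie in [0, 1]")
        if not (self.outside_hu < self.soft_tissue_hu[0] < self.bone_hu[0]):
            raise ValueError("tissue HU means must be ordered air < soft tissue < bone")

    @property
    def origin(self) -> tuple[float, float, float]:
        """Grid origin placing the grid centre at world (0, 0, 0)."""
        return tuple(
            -(n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
        )  # type: ignore[return-value]


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    o = spec.origin
    x = (o[0] + np.arange(spec.shape[0]) * spec.spacing[0])[:, None, None]
    y = (o[1] + np.arange(spec.shape[1]) * spec.spacing[1])[None, :, None]
    z = (o[2] + np.arange(spec.shape[2]) * spec.spacing[2])[None, None, :]
    return x, y, z


def _ellipsoid(x, y, z, centre, radii) -> np.ndarray:
    return (
        ((x - centre[0]) / radii[0]) ** 2
        + ((y - centre[1]) / radii[1]) ** 2
        + ((z - centre[2]) / radii[2]) ** 2
    ) <= 1.0


def _sphere(x, y, z, centre, radius) -> np.ndarray:
    return ((x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2) <= radius**2


def _truncated_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    return sd * np.clip(rng.standard_normal(n), -3.5, 3.5)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, OrganMaskSet]:
    """Build one phantom: HU volume plus organ masks.

    Deterministic in ``spec`` (including ``spec.seed``).  Raises
    :class:`PhantomGeometryError` if the configured geometry makes organs
    overlap or leave the body.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = _world_grids(spec)

    bx, by = spec.body_radii_mm
    body = ((x / bx) ** 2 + (y / by) ** 2) <= 1.0
    body = np.broadcast_to(body, spec.shape).copy()

    fc = spec.femoral_centre_mm
    bone = _sphere(x, y, z, fc, spec.femoral_radius_mm)
    bone |= _sphere(x, y, z, (-fc[0], fc[1], fc[2]), spec.femoral_radius_mm)
    ic = spec.iliac_centre_mm
    for sx in (+1.0, -1.0):
        rod = (
            ((x - sx * ic[0]) ** 2 + (y - ic[1]) ** 2) <= spec.iliac_radius_mm**2
        ) & (np.abs(z) <= spec.iliac_half_length_mm)
        bone |= rod

    bladder = _ellipsoid(x, y, z, spec.bladder_centre_mm, spec.bladder_radii_mm)
    prostate = _ellipsoid(x, y, z, spec.prostate_centre_mm, spec.prostate_radii_mm)
    rc = spec.rectum_centre_mm
    rectum = (
        ((x - rc[0]) ** 2 + (y - rc[1]) ** 2) <= spec.rectum_radius_mm**2
    ) & (np.abs(z) <= spec.rectum_half_length_mm)

    masks = OrganMaskSet(
        body=body,
        bone=np.broadcast_to(bone, spec.shape).copy(),
        bladder=np.broadcast_to(bladder, spec.shape).copy(),
        rectum=np.broadcast_to(rectum, spec.shape).copy(),
        prostate=np.broadcast_to(prostate, spec.shape).copy(),
    )
    masks.validate()

    vol = np.full(spec.shape, spec.outside_hu, dtype=np.float64)

    # Draw tissues in a fixed order so the stream of random numbers is stable.
    for mask, (mean, sd) in (
        (masks.remaining_soft_tissue(), spec.soft_tissue_hu),
        (masks.bone, spec.bone_hu),
        (masks.bladder, spec.bladder_hu),
        (masks.prostate, spec.prostate_hu),
        (masks.rectum, spec.rectum_hu),
    ):
        n = int(mask.sum())
        vol[mask] = mean + _truncated_noise(rng, n, sd)

    if rng.random() < spec.rectal_gas_probability:
        zmax = max(spec.rectum_half_length_mm - spec.gas_radius_mm, 0.0)
        gz = rng.uniform(-zmax, zmax)
        gas = _sphere(x, y, z, (rc[0], rc[1], gz), spec.gas_radius_mm)
        gas = np.broadcast_to(gas, spec.shape) & masks.rectum
        vol[gas] = spec.gas_hu

    np.clip(vol, HU_MIN, HU_MAX, out=vol)
    ct = CTVolume(voxels=vol, spacing=spec.spacing, origin=spec.origin)
    return ct, masks


def jitter_spec(template: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """One patient's spec: per-organ size and tissue-HU variability.

    Organ radii are scaled by a uniform +/-10% factor (one per structure),
    the body by +/-5%; soft-tissue-like means are shifted by +/-10 HU and
    bone by +/-100 HU, mimicking inter-patient density variation.
    """
    s = lambda: float(rng.uniform(0.90, 1.10))  # noqa: E731
    body_f = float(rng.uniform(0.95, 1.05))
    pf, blf, rf, ff, ilf = s(), s(), s(), s(), s()
    d_soft = float(rng.uniform(-10.0, 10.0))
    d_bladder = float(rng.uniform(-10.0, 10.0))
    d_prostate = float(rng.uniform(-10.0, 10.0))
    d_rectum = float(rng.uniform(-10.0, 10.0))
    d_bone = float(rng.uniform(-100.0, 100.0))
    seed = int(rng.integers(0, 2**31 - 1))

    scale3 = lambda t, f: tuple(v * f for v in t)  # noqa: E731
    return replace(
        template,
        body_radii_mm=scale3(template.body_radii_mm, body_f),
        prostate_radii_mm=scale3(template.prostate_radii_mm, pf),
        bladder_radii_mm=scale3(template.bladder_radii_mm, blf),
        rectum_radius_mm=template.rectum_radius_mm * rf,
        femoral_radius_mm=template.femoral_radius_mm * ff,
        iliac_radius_mm=template.iliac_radius_mm * ilf,
        soft_tissue_hu=(template.soft_tissue_hu[0] + d_soft, template.soft_tissue_hu[1]),
        bladder_hu=(template.bladder_hu[0] + d_bladder, template.bladder_hu[1]),
        prostate_hu=(template.prostate_hu[0] + d_prostate, template.prostate_hu[1]),
        rectum_hu=(template.rectum_hu[0] + d_rectum, template.rectum_hu[1]),
        bone_hu=(template.bone_hu[0] + d_bone, template.bone_hu[1]),
        seed=seed,
    )


def cohort(
    spec_template: PhantomSpec | None = None,
    n_patients: int = 39,
    seed: int = 0,
) -> list[tuple[CTVolume, OrganMaskSet]]:
    """Generate a reproducible cohort of jittered phantoms."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    template = spec_template if spec_template is not None else PhantomSpec()
    out = []
    for j in range(n_patients):
        spec_j = jitter_spec(template, np.random.default_rng([seed, j]))
        out.append(generate_phantom(spec_j))
    return out


def mask_centroid(mask: np.ndarray, ct: CTVolume) -> np.ndarray:
    """World-coordinate centroid (mm) of a boolean mask on ``ct``'s grid."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("mask is empty")
    return np.asarray(ct.origin) + idx.mean(axis=0) * np.asarray(ct.spacing)
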