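"""Controlled Hounsfield-unit error injection.

Two error families are supported:

* a spherical *artefact* of configurable intensity offset, diameter and
  distance from the isocentre, displaced along one treatment-beam axis
  (the error model of the factor-screening experiment on error
  intensity / size / location);
* homogeneous *organ-wise mean shifts* applied to bladder, rectum, bone,
  prostate and the remaining soft tissue (the organ-error experiment).

Both are pure functions: the input volume is never mutated, a zero offset
is a bit-exact identity, and shifted HU are clamped at -1000 (air) below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CTVolume, OrganMaskSet

__all__ = [
    "ArtefactSpec",
    "OrganShiftSpec",
    "artefact_centre",
    "insert_artefact",
    "apply_organ_shifts",
]

HU_FLOOR = -1000.0


@dataclass(frozen=True)
class ArtefactSpec:
    """A spherical HU error: offset (HU), size (mm) and location (mm).

    The sphere centre sits ``distance_mm`` from the isocentre along the
    source-to-isocentre direction of beam ``beam_index``.
    """

    delta_hu: float
    diameter_mm: float
    distance_mm: float
    beam_index: int = 0

    def __post_init__(self) -> None:
        if not (-250.0 <= self.delta_hu <= 250.0):
            raise ValueError("delta_hu must lie in [-250, +250] HU")
        if not (2.0 <= self.diameter_mm <= 50.0):
            raise ValueError("diameter_mm must lie in [2, 50] mm")
        if not (0.0 <= self.distance_mm <= 100.0):
            raise ValueError("distance_mm must lie in [0, 100] mm")
        if self.beam_index < 0:
            raise ValueError("beam_index must be non-negative")


@dataclass(frozen=True)
class OrganShiftSpec:
    """Additive mean-HU shifts per structure, in Hounsfield units."""

    bladder: float = 0.0
    rectum: float = 0.0
    bone: float = 0.0
    prostate: float = 0.0
    soft_tissue: float = 0.0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("bladder", -100.0, 100.0),
            ("rectum", -1000.0, 200.0),
            ("bone", -500.0, 500.0),
            ("prostate", -100.0, 100.0),
            ("soft_tissue", -100.0, 100.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} shift {v} HU outside [{lo}, {hi}]")


def artefact_centre(plan, artefact: ArtefactSpec) -> np.ndarray:
    """World position (mm) of the artefact centre for a given plan.

    centre = isocentre + distance * unit(source -> isocentre) of the chosen
    beam, i.e. displacement continues downstream along that beam's axis.
    """
    from .dose import beam_sources  # local import to avoid a cycle

    sources = beam_sources(plan)
    if artefact.beam_index >= len(sources):
        raise ValueError(
            f"beam_index {artefact.beam_index} out of range for a "
            f"{len(sources)}-beam plan"
        )
    iso = np.asarray(plan.isocentre_mm, dtype=float)
    direction = iso - sources[artefact.beam_index]
    direction /= np.linalg.norm(direction)
    return iso + artefact.distance_mm * direction


def _sphere_mask(ct: CTVolume, centre: np.ndarray, radius: float) -> np.ndarray:
    x, y, z = ct.world_axes()
    return (
        (x[:, None, None] - centre[0]) ** 2
        + (y[None, :, None] - centre[1]) ** 2
        + (z[None, None, :] - centre[2]) ** 2
    ) <= radius**2


def insert_artefact(
    ct: CTVolume,
    masks: OrganMaskSet,
    plan,
    artefact: ArtefactSpec,
) -> CTVolume:
    """Return a copy of ``ct`` with the spherical HU offset added.

    Voxels whose centres lie within ``diameter/2`` of the artefact centre
    receive ``delta_hu`` and are clamped at -1000 HU below.  An artefact
    that lies entirely outside the body cannot affect any tissue and is
    rejected as misuse.  A sphere too small to contain any voxel centre is
    a no-op when it falls inside the body (sub-resolution error).
    """
    centre = artefact_centre(plan, artefact)
    voxels = ct.voxels.copy()
    out = CTVolume(voxels=voxels, spacing=ct.spacing, origin=ct.origin)

    sphere = _sphere_mask(ct, centre, artefact.diameter_mm / 2.0)
    if not sphere.any():
        # Sub-voxel sphere: decide inside/outside by the nearest voxel.
        idx = np.clip(
            np.round((centre - np.asarray(ct.origin)) / np.asarray(ct.spacing)).astype(int),
            0,
            np.asarray(ct.shape) - 1,
        )
        if not masks.body[tuple(idx)]:
            raise ValueError("artefact lies entirely outside the body")
        return out
    if not (sphere & masks.body).any():
        raise ValueError("artefact lies entirely outside the body")

    if artefact.delta_hu != 0.0:
        voxels[sphere] = np.maximum(voxels[sphere] + artefact.delta_hu, HU_FLOOR)
    return out


def apply_organ_shifts(
    ct: CTVolume,
    masks: OrganMaskSet,
    shifts: OrganShiftSpec,
) -> CTVolume:
    """Return a copy of ``ct`` with per-structure mean-HU shifts applied.

    The soft-tissue shift targets body minus the four delineated organs;
    air outside the body is untouched.
    """
    if masks.body.shape != ct.shape:
        raise ValueError("mask shape does not match volume shape")
    voxels = ct.voxels.copy()
    for mask, delta in (
        (masks.bladder, shifts.bladder),
        (masks.rectum, shifts.rectum),
        (masks.bone, shifts.bone),
        (masks.prostate, shifts.prostate),
        (masks.remaining_soft_tissue(), shifts.soft_tissue),
    ):
        if delta != 0.0:
            voxels[mask] = np.maximum(voxels[mask] + delta, HU_FLOOR)
    return CTVolume(voxels=voxels, spacing=ct.spacing, origin=ct.origin)
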