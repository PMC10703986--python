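"""Simplified multi-beam photon dose model for isocentre-dose sensitivity.

The engine models a coplanar 6 MV plan (default: 7 equispaced gantry
angles) as primary fluence only: each beam contributes

    weight * exp(-mu_w * WEPL(source, v)) * (SAD / |source - v|)**2

inside a cylindrical field aperture around its axis, where WEPL is the
water-equivalent path length (line integral of relative electron density
obtained from a piecewise-linear HU-to-density calibration).  A single
global normalisation factor, fixed on the *unperturbed* volume so that the
isocentre receives the prescription dose, is reused unchanged for every
perturbed volume of the same patient — mirroring how clinical beam
parameters are copied from a reference plan onto modified images.

Scatter, build-up and in-field divergence are deliberately ignored: the
analysis only requires a dose functional that responds physically
(monotonically, through radiological depth) to HU changes; absolute dose
values away from the normalisation point are not meaningful clinically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import CTVolume

__all__ = [
    "DensityCurve",
    "DEFAULT_CURVE",
    "BeamPlan",
    "DoseGrid",
    "default_plan",
    "beam_sources",
    "hu_to_density",
    "radiological_depth",
    "raw_point_dose",
    "compute_dose",
    "calibrate_plan",
    "isocentre_dose",
    "IsocentreDoseModel",
]


@dataclass(frozen=True)
class DensityCurve:
    """Piecewise-linear HU -> relative electron density calibration.

    Anchored at air (-1000 HU -> 0.0) and water (0 HU -> 1.0); clamped to
    its endpoint densities outside the control-point range.
    """

    hu: tuple[float, ...] = (-1000.0, 0.0, 1000.0, 3000.0)
    density: tuple[float, ...] = (0.0, 1.0, 1.6, 2.1)

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        rho = np.asarray(self.density, dtype=float)
        if hu.size != rho.size or hu.size < 2:
            raise ValueError("curve needs >= 2 matching (hu, density) control points")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU control points must be strictly increasing")
        if np.any(np.diff(rho) < 0):
            raise ValueError("density must be monotone non-decreasing in HU")
        if abs(float(np.interp(-1000.0, hu, rho))) > 1e-12:
            raise ValueError("curve must map -1000 HU (air) to density 0")
        if abs(float(np.interp(0.0, hu, rho)) - 1.0) > 1e-12:
            raise ValueError("curve must map 0 HU (water) to density 1")

    def __call__(self, hu):
        return np.interp(hu, self.hu, self.density)


DEFAULT_CURVE = DensityCurve()


def hu_to_density(hu, curve: DensityCurve = DEFAULT_CURVE):
    """Relative electron density for HU value(s), clamped at curve ends."""
    return curve(hu)


@dataclass
class BeamPlan:
    """Beam geometry, attenuation model and prescription for one patient.

    Gantry angle 0 deg places the source anterior to the patient (LPS
    -y), 90 deg at the patient's left (+x); beams are coplanar in the
    transverse plane through the isocentre.
    """

    isocentre_mm: tuple[float, float, float]
    gantry_angles_deg: tuple[float, ...] = tuple(i * 360.0 / 7.0 for i in range(7))
    sad_mm: float = 1000.0
    mu_w_per_mm: float = 0.0049
    beam_weights: tuple[float, ...] | None = None
    aperture_mm: float = 40.0
    prescription_gy: float = 78.0
    fractions: int = 39
    grid_mm: float = 3.0
    normalisation: float | None = None

    def __post_init__(self) -> None:
        if len(self.gantry_angles_deg) < 1:
            raise ValueError("plan needs at least one beam")
        if self.beam_weights is None:
            self.beam_weights = tuple(1.0 for _ in self.gantry_angles_deg)
        if len(self.beam_weights) != len(self.gantry_angles_deg):
            raise ValueError("one weight per beam required")
        if any(w < 0 for w in self.beam_weights) or sum(self.beam_weights) <= 0:
            raise ValueError("beam weights must be non-negative with positive sum")
        if self.sad_mm <= 0 or self.mu_w_per_mm <= 0 or self.aperture_mm <= 0:
            raise ValueError("sad_mm, mu_w_per_mm and aperture_mm must be positive")
        if self.prescription_gy <= 0 or self.fractions < 1:
            raise ValueError("invalid prescription")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.prescription_gy / self.fractions


def default_plan(isocentre_mm, **overrides) -> BeamPlan:
    """The study's default plan: 7 equispaced coplanar 6 MV beams, 78 Gy."""
    return BeamPlan(isocentre_mm=tuple(float(c) for c in isocentre_mm), **overrides)


def beam_sources(plan: BeamPlan) -> np.ndarray:
    """(B, 3) world positions of the beam sources, mm."""
    iso = np.asarray(plan.isocentre_mm, dtype=float)
    ang = np.deg2rad(np.asarray(plan.gantry_angles_deg, dtype=float))
    offsets = np.stack(
        [np.sin(ang), -np.cos(ang), np.zeros_like(ang)], axis=1
    ) * plan.sad_mm
    return iso + offsets


@dataclass(frozen=True)
class DoseGrid:
    """3-D dose distribution in Gy on its own regular grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")


def _density_volume(ct: CTVolume, curve: DensityCurve) -> np.ndarray:
    return np.interp(ct.voxels, curve.hu, curve.density)


def _clip_segments(source: np.ndarray, targets: np.ndarray,
                   lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slab-clip rays source->target (t in [0,1]) to the box [lo, hi]."""
    d = targets - source
    t0 = np.zeros(len(targets))
    t1 = np.ones(len(targets))
    for a in range(3):
        da = d[:, a]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo[a] - source[a]) / da
            tb = (hi[a] - source[a]) / da
        tmin = np.minimum(ta, tb)
        tmax = np.maximum(ta, tb)
        par = da == 0.0
        inside = (source[a] >= lo[a]) & (source[a] <= hi[a])
        tmin = np.where(par, np.where(inside, -np.inf, np.inf), tmin)
        tmax = np.where(par, np.where(inside, np.inf, -np.inf), tmax)
        t0 = np.maximum(t0, tmin)
        t1 = np.minimum(t1, tmax)
    return t0, np.maximum(t1, t0)  # empty intersection -> zero length


def _wepl_batch(dens: np.ndarray, spacing: np.ndarray, origin: np.ndarray,
                source: np.ndarray, targets: np.ndarray, step: float) -> np.ndarray:
    """Water-equivalent path lengths (mm) from one source to many targets."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    lo = origin
    hi = origin + (np.asarray(dens.shape) - 1) * spacing
    seg = targets - source
    length = np.linalg.norm(seg, axis=1)
    t0, t1 = _clip_segments(source, targets, lo, hi)
    seg_len = (t1 - t0) * length
    max_len = float(seg_len.max(initial=0.0))
    if max_len <= 0.0:
        return np.zeros(len(targets))
    k = int(np.ceil(max_len / step))
    frac = (np.arange(k) + 0.5) / k
    ts = t0[:, None] + (t1 - t0)[:, None] * frac[None, :]
    pts = source[None, None, :] + ts[:, :, None] * seg[:, None, :]
    idx = (pts - origin) / spacing
    vals = map_coordinates(
        dens, idx.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
    ).reshape(len(targets), k)
    return vals.sum(axis=1) * (seg_len / k)


def radiological_depth(
    ct: CTVolume,
    curve: DensityCurve,
    source_mm,
    target_mm,
    step_mm: float | None = None,
) -> float:
    """Line integral of relative electron density from source to target, mm.

    Uniform fine sampling with step <= half the smallest voxel dimension
    (the default); regions outside the volume contribute zero (air).
    """
    lo, hi = ct.world_extent()
    target = np.asarray(target_mm, dtype=float)
    if np.any(target < lo) or np.any(target > hi):
        raise ValueError("target lies outside the volume bounds")
    if step_mm is None:
        step_mm = min(ct.spacing) / 2.0
    dens = _density_volume(ct, curve)
    return float(
        _wepl_batch(
            dens,
            np.asarray(ct.spacing, dtype=float),
            np.asarray(ct.origin, dtype=float),
            np.asarray(source_mm, dtype=float),
            target[None, :],
            step_mm,
        )[0]
    )


def _beam_dose(dens, spacing, origin, plan, points, step,
               chunk_samples: int = 4_000_000) -> np.ndarray:
    """Unnormalised dose at world ``points`` (N, 3), summed over beams."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    iso = np.asarray(plan.isocentre_mm, dtype=float)
    total = np.zeros(len(points))
    for source, weight in zip(beam_sources(plan), plan.beam_weights):
        if weight == 0.0:
            continue
        axis = iso - source
        axis /= np.linalg.norm(axis)
        rel = points - source
        perp = rel - (rel @ axis)[:, None] * axis[None, :]
        in_field = np.linalg.norm(perp, axis=1) <= plan.aperture_mm
        if not in_field.any():
            continue
        tgt = points[in_field]
        dist = np.linalg.norm(tgt - source, axis=1)
        # chunk long batches to bound the sample-coordinate memory
        n_chunk = max(1, chunk_samples // max(1, int(plan.sad_mm / step)))
        wepl = np.empty(len(tgt))
        for s in range(0, len(tgt), n_chunk):
            wepl[s:s + n_chunk] = _wepl_batch(
                dens, spacing, origin, source, tgt[s:s + n_chunk], step
            )
        contrib = weight * np.exp(-plan.mu_w_per_mm * wepl) * (plan.sad_mm / dist) ** 2
        total[in_field] += contrib
    return total


def raw_point_dose(
    ct: CTVolume,
    plan: BeamPlan,
    points,
    curve: DensityCurve = DEFAULT_CURVE,
    step_mm: float | None = None,
    _density: np.ndarray | None = None,
):
    """Unnormalised primary-fluence dose at one or more world points."""
    if step_mm is None:
        step_mm = min(ct.spacing) / 2.0
    dens = _density if _density is not None else _density_volume(ct, curve)
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    out = _beam_dose(
        dens,
        np.asarray(ct.spacing, dtype=float),
        np.asarray(ct.origin, dtype=float),
        plan,
        pts,
        step_mm,
    )
    return float(out[0]) if single else out


def _check_isocentre_in_body(ct: CTVolume, plan: BeamPlan) -> None:
    lo, hi = ct.world_extent()
    iso = np.asarray(plan.isocentre_mm, dtype=float)
    if np.any(iso < lo) or np.any(iso > hi):
        raise ValueError("isocentre lies outside the volume")
    idx = np.round((iso - lo) / np.asarray(ct.spacing)).astype(int)
    if ct.voxels[tuple(idx)] < -500.0:
        raise ValueError("isocentre appears to lie outside the body (air-like HU)")


def _dose_grid_geometry(ct: CTVolume, grid_mm: float):
    lo, hi = ct.world_extent()
    n = np.maximum(np.floor((hi - lo) / grid_mm).astype(int) + 1, 2)
    return lo, (grid_mm, grid_mm, grid_mm), tuple(int(v) for v in n)


def _interp_grid(values: np.ndarray, spacing, origin, point) -> float:
    idx = (np.asarray(point, dtype=float) - np.asarray(origin)) / np.asarray(spacing)
    if np.any(idx < 0) or np.any(idx > np.asarray(values.shape) - 1):
        raise ValueError("point lies outside the dose grid")
    return float(map_coordinates(values, idx[:, None], order=1, mode="nearest")[0])


def compute_dose(
    ct: CTVolume,
    plan: BeamPlan,
    curve: DensityCurve = DEFAULT_CURVE,
    step_mm: float | None = None,
) -> DoseGrid:
    """Full 3-D dose on an isotropic grid (default 3 mm) covering the CT.

    If ``plan.normalisation`` is unset, the plan is treated as the
    reference: the grid is scaled so the trilinearly-interpolated dose at
    the isocentre equals the prescription.  Pass a plan calibrated with
    :func:`calibrate_plan` to reuse a reference normalisation on perturbed
    volumes.
    """
    _check_isocentre_in_body(ct, plan)
    if step_mm is None:
        step_mm = min(ct.spacing) / 2.0
    dens = _density_volume(ct, curve)
    origin, spacing, shape = _dose_grid_geometry(ct, plan.grid_mm)
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    raw = _beam_dose(
        dens,
        np.asarray(ct.spacing, dtype=float),
        np.asarray(ct.origin, dtype=float),
        plan,
        points,
        step_mm,
    ).reshape(shape)
    if plan.normalisation is None:
        raw_iso = _interp_grid(raw, spacing, origin, plan.isocentre_mm)
        if raw_iso <= 0.0:
            raise ValueError("zero dose at the isocentre; cannot normalise")
        factor = plan.prescription_gy / raw_iso
    else:
        factor = plan.normalisation
    return DoseGrid(values=raw * factor, spacing=spacing, origin=tuple(origin))


def calibrate_plan(
    ct: CTVolume,
    plan: BeamPlan,
    curve: DensityCurve = DEFAULT_CURVE,
    step_mm: float | None = None,
) -> BeamPlan:
    """Fix the plan's grid-dose normalisation on an unperturbed volume."""
    _check_isocentre_in_body(ct, plan)
    if step_mm is None:
        step_mm = min(ct.spacing) / 2.0
    dens = _density_volume(ct, curve)
    origin, spacing, shape = _dose_grid_geometry(ct, plan.grid_mm)
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    raw = _beam_dose(
        dens,
        np.asarray(ct.spacing, dtype=float),
        np.asarray(ct.origin, dtype=float),
        plan,
        points,
        step_mm,
    ).reshape(shape)
    raw_iso = _interp_grid(raw, spacing, origin, plan.isocentre_mm)
    if raw_iso <= 0.0:
        raise ValueError("zero dose at the isocentre; cannot normalise")
    return dataclasses.replace(plan, normalisation=plan.prescription_gy / raw_iso)


def isocentre_dose(dose: DoseGrid, plan: BeamPlan) -> float:
    """Trilinear interpolation of the dose grid at the plan isocentre, Gy."""
    return _interp_grid(dose.values, dose.spacing, dose.origin, plan.isocentre_mm)


class IsocentreDoseModel:
    """Fast scalar dose functional f(CT) = dose at the isocentre, Gy.

    Evaluates the primary-fluence model directly at the isocentre point
    (no dose grid), with its own normalisation fixed on the baseline
    volume so the unperturbed isocentre dose equals the prescription
    exactly.  This is the model the screening and sweep analyses evaluate
    hundreds of times per patient.
    """

    def __init__(
        self,
        baseline_ct: CTVolume,
        plan: BeamPlan,
        curve: DensityCurve = DEFAULT_CURVE,
        step_mm: float | None = None,
    ) -> None:
        _check_isocentre_in_body(baseline_ct, plan)
        self.plan = plan
        self.curve = curve
        self.step_mm = step_mm if step_mm is not None else min(baseline_ct.spacing) / 2.0
        raw0 = raw_point_dose(baseline_ct, plan, plan.isocentre_mm, curve, self.step_mm)
        if raw0 <= 0.0:
            raise ValueError("zero baseline dose at the isocentre; cannot normalise")
        self.normalisation = plan.prescription_gy / raw0

    def __call__(self, ct: CTVolume) -> float:
        return self.normalisation * raw_point_dose(
            ct, self.plan, self.plan.isocentre_mm, self.curve, self.step_mm
        )
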