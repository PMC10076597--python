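"""Synthetic CECT phantoms with exact ground truth.

No public microCT volumes accompany the staining studies this package
analyses, so every analysis is validated against generated scenes whose
true quantities are known by construction:

* **Staining scenes** — a quasi-spherical half-ellipsoid "hemisphere"
  inside an Eppendorf-tube annulus with a ceramic bead and air in the
  field of view.  At time ``t`` (days) a stained shell of depth
  ``r_p(t) = R_e (1 - exp(-k t))`` has advanced inward from every exposed
  surface; the tissue can swell or shrink (a volume-based factor tracking
  staining progress) and i.i.d. Gaussian acquisition noise is added last.
* **Fiber phantoms** — parallel cylindrical fiber bundles at a chosen
  radius and analytic volume fraction, hypo- or hyperintense against the
  background, with a demyelination factor that shrinks the fiber/background
  contrast towards zero (demyelinated white matter admits more of an
  anionic stain and brightens).

Every scene returns a *manifest* holding the generative truth (volumes,
front depth, compartment gray levels, fiber axes, reference VOIs, noise
clipping fraction) so downstream measurements can be checked analytically.
The staining-solution molarity arithmetic used to plan staining baths is
also housed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ContractError, GeometryError
from .volume import GrayVolume, Voi

__all__ = [
    "PhantomSpec",
    "StainingSolutionSpec",
    "make_scene",
    "make_timeseries",
    "make_fiber_phantom",
    "molarity_from_mass_percent",
]

_U16_MAX = 65535.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative specification of a synthetic CECT scene.

    Gray levels follow the attenuation convention (0 = air-like, 65535 =
    densest).  Defaults emulate a fast-penetrating, swelling-inducing
    anionic stain (Hexabrix-like): full staining within the nine-day
    window, +7 % total tissue swelling, hypointense fiber bundles.

    The spatial scale is chosen so the whole hemisphere fits a 128-cube:
    30 um voxels give a 3.84 mm field of view around ellipsoid radii of
    (1.50, 1.35, 1.20) mm.
    """

    shape: Tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 30.0
    ellipsoid_radii_mm: Tuple[float, float, float] = (1.50, 1.35, 1.20)
    # scene gray levels (16-bit)
    air_gray: float = 2000.0
    tube_gray: float = 12000.0
    bead_gray: float = 55000.0
    unstained_gray: float = 15000.0
    stained_gray: float = 35000.0
    # staining kinetics
    rate_per_day: float = 0.5
    total_volume_change_pct: float = 7.0
    front_blur_vox: float = 1.0
    # fiber system
    fiber_direction: Tuple[float, float, float] = (1.0, 0.0, 0.0)  # along z
    fiber_radius_um: float = 30.0
    fiber_volume_fraction: float = 0.20
    fiber_polarity: Literal["hypo", "hyper"] = "hypo"
    fiber_contrast: float = 8000.0
    demyelination: float = 0.0
    background_gray: float = 30000.0
    # acquisition noise
    noise_sd: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        grays = (
            self.air_gray,
            self.tube_gray,
            self.bead_gray,
            self.unstained_gray,
            self.stained_gray,
            self.background_gray,
        )
        if any(not 0 <= g <= _U16_MAX for g in grays):
            raise ContractError("gray levels must lie within the 16-bit range")
        if not 0 <= self.demyelination <= 1:
            raise ContractError("demyelination factor must lie in [0, 1]")
        if not self.rate_per_day > 0:
            raise ContractError("rate_per_day must be positive")
        if not 0 < self.fiber_volume_fraction <= 0.5:
            raise ContractError("fiber volume fraction must lie in (0, 0.5]")
        if np.linalg.norm(self.fiber_direction) == 0:
            raise ContractError("fiber direction must be non-zero")


@dataclass(frozen=True)
class StainingSolutionSpec:
    """A staining solution: mass-per-volume concentration and molar mass.

    ``molarity_mmol_per_l`` is derived:  (m/V% x 10) g/L divided by the
    molecular weight in g/mol, expressed in mmol/L.
    """

    name: str
    mass_per_volume_pct: float
    molecular_weight: float

    def __post_init__(self) -> None:
        if self.mass_per_volume_pct <= 0 or self.molecular_weight <= 0:
            raise ContractError("concentration and molecular weight must be positive")

    @property
    def molarity_mmol_per_l(self) -> float:
        return molarity_from_mass_percent(self.mass_per_volume_pct, self.molecular_weight)


def molarity_from_mass_percent(mass_percent: float, mw: float) -> float:
    """Convert a m/V% concentration (g per 100 mL) to mmol/L.

    ``mass_percent`` g/100 mL is ``10 x mass_percent`` g/L; dividing by
    the molecular weight (g/mol) and scaling to mmol gives
    ``mass_percent * 10 / mw * 1000``.
    """
    if mass_percent <= 0 or mw <= 0:
        raise ContractError("mass_percent and mw must be positive")
    return mass_percent * 10.0 / mw * 1000.0


# --------------------------------------------------------------------------
# staining scene
# --------------------------------------------------------------------------

def _rng_for(spec: PhantomSpec, stream: Tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=stream))


def _scene_geometry(spec: PhantomSpec, swell_factor: float):
    """Masks of tissue, tube annulus, bead; plus reference VOIs."""
    nz, ny, nx = spec.shape
    vox_mm = spec.voxel_size_um / 1000.0
    radii_vox = [
        r * swell_factor ** (1.0 / 3.0) / vox_mm for r in spec.ellipsoid_radii_mm
    ]
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    if 2 * max(radii_vox) > min(spec.shape) - 10:
        raise GeometryError("hemisphere does not fit inside the grid")
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    ell = (
        ((zz - cz) / radii_vox[0]) ** 2
        + ((yy - cy) / radii_vox[1]) ** 2
        + ((xx - cx) / radii_vox[2]) ** 2
    ) <= 1.0
    tissue = ell & (zz >= cz)  # half-ellipsoid: flat cut at the mid-plane

    r_plane = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    tube_outer = min(ny, nx) / 2.0 - 2.0
    tube_inner = tube_outer - 4.0
    tube = (r_plane >= tube_inner) & (r_plane <= tube_outer)
    tube = np.broadcast_to(tube, spec.shape)

    bead_r = 4.0
    bead_center = (int(cz), int(cy + radii_vox[1] + 8), int(cx))
    if bead_center[1] + bead_r >= tube_inner + cy:
        bead_center = (int(cz), int((cy + radii_vox[1] + tube_inner + cy) / 2), int(cx))
    bead = (
        (zz - bead_center[0]) ** 2 + (yy - bead_center[1]) ** 2 + (xx - bead_center[2]) ** 2
    ) <= bead_r**2

    ref_vois = {
        "bead": Voi.sphere(bead_center, bead_r - 1.0),
        "tube": Voi.box(
            (2, int(cy - 1), int(cx - tube_outer + 1)), (nz - 4, 3, 2)
        ),
        "air": Voi.box((2, int(cy - 3), int(cx - 3)), (8, 6, 6)),
    }
    return tissue, tube, bead, ref_vois


def make_scene(spec: PhantomSpec, t_days: float) -> Tuple[GrayVolume, dict]:
    """One staining scene at time ``t_days`` plus its truth manifest.

    The staining front advances inward from every exposed surface
    (graded by the Euclidean distance transform of the tissue mask) and
    is placed so that the remaining unstained core volume equals the
    spherical-model prediction ``V_u(t) = 4/3 pi (R_e - r_p(t))^3`` with
    ``r_p(t) = R_e (1 - exp(-k t))`` and ``R_e`` the sphere-equivalent
    radius of the whole specimen.  The front *shape* therefore follows
    the true half-ellipsoid geometry while the front *position over
    time* realises the kinetic law the analysis estimates, so the
    generative (R_e, k) are the quantities the pipeline should recover.
    """
    if t_days < 0:
        raise ContractError("t_days must be non-negative")
    vox_mm = spec.voxel_size_um / 1000.0
    progress = 1.0 - math.exp(-spec.rate_per_day * t_days)
    swell = 1.0 + spec.total_volume_change_pct / 100.0 * progress
    tissue, tube, bead, ref_vois = _scene_geometry(spec, swell)

    n_tissue = int(tissue.sum())
    v_e = n_tissue * vox_mm**3
    r_e_sphere = (3.0 * v_e / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_p = r_e_sphere * progress

    v_u_target = (4.0 / 3.0) * math.pi * (r_e_sphere - r_p) ** 3
    n_u = int(round(v_u_target / vox_mm**3))
    depth = ndimage.distance_transform_edt(tissue)
    if n_u <= 0:
        stained = tissue.copy()
    elif n_u >= n_tissue:
        stained = np.zeros_like(tissue)
    else:
        tissue_depths = depth[tissue]
        # n_u deepest voxels stay unstained
        d_star = np.partition(tissue_depths, n_tissue - n_u)[n_tissue - n_u]
        stained = tissue & (depth < d_star)
    unstained = tissue & ~stained
    v_u = float(unstained.sum()) * vox_mm**3

    scene = np.full(spec.shape, spec.air_gray, dtype=np.float64)
    scene[tube] = spec.tube_gray
    if spec.front_blur_vox > 0:
        frac = ndimage.gaussian_filter(stained.astype(np.float64), spec.front_blur_vox)
        tissue_gray = spec.unstained_gray + (spec.stained_gray - spec.unstained_gray) * frac
        scene[tissue] = tissue_gray[tissue]
    else:
        scene[unstained] = spec.unstained_gray
        scene[stained] = spec.stained_gray
    scene[bead] = spec.bead_gray

    rng = _rng_for(spec, (int(round(t_days * 1000)),))
    noisy = scene + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    clipped = float(((noisy < 0) | (noisy > _U16_MAX)).mean())
    voxels = np.clip(np.rint(noisy), 0, _U16_MAX).astype(np.uint16)

    manifest = {
        "t_days": t_days,
        "v_entire_mm3": v_e,
        "v_unstained_mm3": v_u,
        "r_entire_sphere_mm": r_e_sphere,
        "r_penetration_mm": r_p,
        "ellipsoid_radii_mm": tuple(
            r * swell ** (1.0 / 3.0) for r in spec.ellipsoid_radii_mm
        ),
        "swell_factor": swell,
        "compartment_grays": {
            "air": spec.air_gray,
            "tube": spec.tube_gray,
            "bead": spec.bead_gray,
            "unstained": spec.unstained_gray,
            "stained": spec.stained_gray,
        },
        "reference_vois": ref_vois,
        "tissue_mask": tissue,
        "stained_mask": stained,
        "noise_sd": spec.noise_sd,
        "clipped_fraction": clipped,
        "seed": spec.seed,
    }
    return GrayVolume(voxels, spec.voxel_size_um), manifest


def make_timeseries(
    spec: PhantomSpec, times_days: Sequence[float] = (1.0, 2.0, 4.0, 9.0)
) -> list[Tuple[GrayVolume, dict]]:
    """Scenes at several staining durations with independent noise.

    The default time points (1, 2, 4 and 9 days) are the staining
    schedule of a time-lapsed penetration experiment.  Noise streams are
    derived per time point from the spec seed, so the series is
    deterministic yet independently noisy.
    """
    if len(times_days) == 0:
        raise ContractError("need at least one time point")
    return [make_scene(spec, float(t)) for t in times_days]


# --------------------------------------------------------------------------
# fiber phantom
# --------------------------------------------------------------------------

def make_fiber_phantom(spec: PhantomSpec) -> Tuple[GrayVolume, dict]:
    """Parallel-cylinder fiber phantom with analytic volume fraction.

    Cylinders of ``fiber_radius_um`` run along ``fiber_direction``
    (currently the z axis) through a centred fiber box, tiled on a
    periodic square lattice whose spacing realises the requested volume
    fraction exactly (partial cylinders wrap across the box, so the
    analytic fraction pi r^2 / s^2 holds without edge bias).  The fiber
    gray is offset from the background by ``fiber_contrast`` in the
    hypo- or hyperintense direction, scaled by ``1 - demyelination``; the
    edge is blurred by ``front_blur_vox`` and Gaussian noise is added.

    Reference materials (bead and tube slabs) sit in the margin outside
    the fiber box so normalized-gray analyses run on the phantom too.
    """
    d = np.asarray(spec.fiber_direction, float)
    d = d / np.linalg.norm(d)
    if abs(d[0]) < 0.999:
        raise ContractError("fiber phantoms currently support the z direction only")
    nz, ny, nx = spec.shape
    r_vox = spec.fiber_radius_um / spec.voxel_size_um
    if r_vox < 1:
        raise ContractError("fiber radius below one voxel")
    margin = 12
    box_y = ny - 2 * margin
    box_x = nx - 2 * margin
    if box_y <= 4 * r_vox or box_x <= 4 * r_vox:
        raise GeometryError("fiber box too small for the requested radius")

    # periodic lattice: vf = pi r^2 / (s_y s_x).  Search lattice counts and
    # a possibly shrunk x-box so the realised fraction hits the request.
    best = None
    n_y_max = max(1, int(box_y // (2 * r_vox)))
    for n_y in range(1, n_y_max + 1):
        s_y = box_y / n_y
        for bx in range(int(4 * r_vox), box_x + 1):
            n_x_max = max(1, int(bx // (2 * r_vox)))
            for n_x in range(1, n_x_max + 1):
                s_x = bx / n_x
                vf = math.pi * r_vox**2 / (s_y * s_x)
                err = abs(vf - spec.fiber_volume_fraction)
                if best is None or err < best[0]:
                    best = (err, n_y, n_x, bx)
    _, n_y, n_x, box_x = best  # type: ignore[misc]
    s_y = box_y / n_y
    s_x = box_x / n_x
    analytic_vf = math.pi * r_vox**2 / (s_y * s_x)
    if analytic_vf > 0.5:
        raise ContractError("requested packing exceeds 0.5 volume fraction")

    yy, xx = np.mgrid[0:box_y, 0:box_x].astype(float)
    fiber2d = np.zeros((box_y, box_x), dtype=bool)
    axes = []
    for iy in range(n_y):
        for ix in range(n_x):
            cyv = (iy + 0.5) * s_y - 0.5
            cxv = (ix + 0.5) * s_x - 0.5
            dy = np.abs(yy - cyv)
            dy = np.minimum(dy, box_y - dy)  # periodic wrap inside the box
            dx = np.abs(xx - cxv)
            dx = np.minimum(dx, box_x - dx)
            fiber2d |= dy**2 + dx**2 <= r_vox**2
            axes.append((cyv + margin, cxv + margin))

    fiber = np.zeros(spec.shape, dtype=bool)
    fiber[:, margin : margin + box_y, margin : margin + box_x] = fiber2d[None]

    sign = -1.0 if spec.fiber_polarity == "hypo" else 1.0
    offset = sign * spec.fiber_contrast * (1.0 - spec.demyelination)
    scene = np.full(spec.shape, spec.background_gray, dtype=np.float64)
    if spec.front_blur_vox > 0:
        frac = ndimage.gaussian_filter(fiber.astype(np.float64), spec.front_blur_vox)
        scene += offset * frac
    else:
        scene[fiber] += offset

    # reference materials in the front margin corners
    bead_voi = Voi.box((2, 2, 2), (6, 6, 6))
    tube_voi = Voi.box((2, 2, nx - 8), (6, 6, 6))
    air_voi = Voi.box((nz - 8, 2, 2), (6, 6, 6))
    scene[bead_voi.contains_mask(spec.shape)] = spec.bead_gray
    scene[tube_voi.contains_mask(spec.shape)] = spec.tube_gray
    scene[air_voi.contains_mask(spec.shape)] = spec.air_gray

    rng = _rng_for(spec, (777,))
    noisy = scene + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    clipped = float(((noisy < 0) | (noisy > _U16_MAX)).mean())
    voxels = np.clip(np.rint(noisy), 0, _U16_MAX).astype(np.uint16)

    fiber_voi = Voi.box((0, margin, margin), (nz, box_y, box_x))
    manifest = {
        "analytic_volume_fraction": analytic_vf,
        "fiber_mask": fiber,
        "fiber_radius_vox": r_vox,
        "fiber_axes_yx": axes,
        "fiber_direction": tuple(d),
        "fiber_gray": spec.background_gray + offset,
        "background_gray": spec.background_gray,
        "contrast_offset": offset,
        "polarity": spec.fiber_polarity,
        "demyelination": spec.demyelination,
        "fiber_voi": fiber_voi,
        "reference_vois": {"bead": bead_voi, "tube": tube_voi, "air": air_voi},
        "compartment_grays": {
            "bead": spec.bead_gray,
            "tube": spec.tube_gray,
            "air": spec.air_gray,
        },
        "noise_sd": spec.noise_sd,
        "clipped_fraction": clipped,
        "seed": spec.seed,
    }
    return GrayVolume(voxels, spec.voxel_size_um), manifest
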