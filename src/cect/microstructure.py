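"""White-matter microstructure metrics from gray-value volumes.

Myelinated fiber bundles appear as oriented tubular structures whose
contrast against the surrounding tissue depends on the staining agent
(hypointense for anionic agents such as Hexabrix, weakly hyperintense for
cationic CA4+).  Four quantities characterise them:

* **Structure-tensor fractional anisotropy (FA)** — a DTI-like parameter
  computed from image gradients rather than water diffusion.  Gaussian
  derivative gradients (scale ``sigma_grad``) are formed into per-voxel
  outer products, smoothed once at ``sigma_tensor`` and again at the
  fiber scale ``sigma_fiber``.  Because image gradients lie perpendicular
  to a fiber's axis, the fiber direction is the eigenvector of the
  *smallest* eigenvalue.  FA uses the standard normalized eigenvalue
  dispersion; the radial-diffusivity analog is the mean of the two minor
  eigenvalues.
* **Fiber volume fraction** — fraction of a VOI on the fiber side of a
  fixed gray threshold on the normalized scale.
* **Fiber detection and labeling** — normalized cross-correlation with
  oriented cylinder templates, then marker-based watershed inside the
  detection mask to split the detection into individual bundles.
* **Thickness** — local thickness (diameter of the largest inscribed
  sphere through each voxel, from the Euclidean distance transform),
  averaged per bundle, with the median across bundles as the headline
  statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import ContractError
from .normalization import ReferenceGrayValues, normalized_gray
from .volume import GrayVolume, Mask, Voi

__all__ = [
    "TensorField",
    "FaResult",
    "FiberLabels",
    "ThicknessReport",
    "GrayValueReport",
    "structure_tensor",
    "fractional_anisotropy",
    "volume_fraction",
    "detect_fibers",
    "label_fibers",
    "fiber_thickness",
    "local_thickness",
    "regional_gray_report",
]


# --------------------------------------------------------------------------
# structure tensor / FA
# --------------------------------------------------------------------------

@dataclass
class TensorField:
    """Per-voxel symmetric orientation tensor, stored as 6 components.

    Component order is ``(zz, zy, zx, yy, yx, xx)``.  Eigenvalues are
    sorted descending; the fiber direction is the minor eigenvector.
    """

    components: np.ndarray  # shape (6, z, y, x)
    sigma_grad: float
    sigma_tensor: float
    sigma_fiber: float
    _eig: Optional[Tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.components.shape[1:]  # type: ignore[return-value]

    def as_matrices(self) -> np.ndarray:
        """Dense (z, y, x, 3, 3) symmetric matrices."""
        zz, zy, zx, yy, yx, xx = self.components
        m = np.empty(self.shape + (3, 3))
        m[..., 0, 0] = zz
        m[..., 0, 1] = m[..., 1, 0] = zy
        m[..., 0, 2] = m[..., 2, 0] = zx
        m[..., 1, 1] = yy
        m[..., 1, 2] = m[..., 2, 1] = yx
        m[..., 2, 2] = xx
        return m

    def eigen(self) -> Tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (z,y,x,3) descending and eigenvectors (z,y,x,3,3).

        ``vecs[..., i, :]`` is the eigenvector of ``vals[..., i]`` in
        (z, y, x) component order.  Results are cached.
        """
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.as_matrices())
            order = np.argsort(vals, axis=-1)[..., ::-1]
            vals = np.take_along_axis(vals, order, axis=-1)
            vecs = np.take_along_axis(
                np.swapaxes(vecs, -1, -2), order[..., None], axis=-2
            )
            self._eig = (vals, vecs)
        return self._eig

    def trace(self) -> np.ndarray:
        zz, _, _, yy, _, xx = self.components
        return zz + yy + xx

    def fiber_directions(self) -> np.ndarray:
        """Unit minor eigenvectors (z, y, x, 3): the local fiber axis."""
        _, vecs = self.eigen()
        return vecs[..., 2, :]


@dataclass
class FaResult:
    """Per-voxel FA map with the radial-diffusivity analog."""

    fa: np.ndarray
    radial: np.ndarray
    energy_floor: float

    def summary(self, mask: Optional[np.ndarray] = None) -> Dict[str, float]:
        sel = np.ones(self.fa.shape, bool) if mask is None else np.asarray(mask, bool)
        fa = self.fa[sel]
        rad = self.radial[sel]
        return {
            "fa_mean": float(fa.mean()),
            "fa_sd": float(fa.std()),
            "radial_mean": float(rad.mean()),
            "radial_sd": float(rad.std()),
            "n": int(fa.size),
        }


def structure_tensor(
    v: Union[GrayVolume, np.ndarray],
    sigma_grad: float = 0.5,
    sigma_tensor: float = 0.5,
    sigma_fiber: float = 5.0,
) -> TensorField:
    """Two-stage smoothed gradient structure tensor of a volume.

    The defaults (0.5, 0.5, 5 voxels) are the mouse-brain settings: a
    sub-voxel derivative scale resolves individual fiber walls while the
    5-voxel fiber-scale smoothing pools orientation over a bundle
    cross-section.  All scales are Gaussian sigmas in voxel units.
    """
    x = v.voxels if isinstance(v, GrayVolume) else np.asarray(v)
    x = x.astype(np.float64)
    for s in (sigma_grad, sigma_tensor, sigma_fiber):
        if not s > 0:
            raise ContractError("all smoothing scales must be positive")
    if min(x.shape) < 6 * max(sigma_grad, sigma_tensor, sigma_fiber):
        raise ContractError(
            f"volume shape {x.shape} smaller than 6*sigma in some axis"
        )
    grads = [
        ndimage.gaussian_filter(x, sigma_grad, order=tuple(int(a == i) for a in range(3)))
        for i in range(3)
    ]
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    comps = np.stack(
        [
            ndimage.gaussian_filter(
                ndimage.gaussian_filter(grads[i] * grads[j], sigma_tensor),
                sigma_fiber,
            )
            for i, j in pairs
        ]
    )
    return TensorField(comps, sigma_grad, sigma_tensor, sigma_fiber)


def fractional_anisotropy(
    tf: TensorField, energy_floor: Optional[float] = None
) -> FaResult:
    """Standard DTI fractional anisotropy of the tensor eigenvalues.

        FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||

    Voxels whose tensor trace falls below ``energy_floor`` (default:
    1e-6 of the maximum trace) carry no orientation signal and are set to
    FA 0.

    The radial-diffusivity analog is ``(lambda_2 + lambda_3) / 2`` of the
    *trace-normalized* eigenvalues.  Raw structure-tensor eigenvalues
    scale with the squared image contrast, so the raw minor-eigenvalue
    mean would fall when fibers lose contrast — opposite to the
    diffusion quantity it mimics.  On the normalized spectrum the analog
    is a pure orientation-dispersion measure (1/3 for isotropy, smaller
    for coherent fibers) and rises as fiber contrast is lost, matching
    the DTI behaviour under demyelination.  Sub-floor voxels are set to
    the isotropic value 1/3.
    """
    vals, _ = tf.eigen()
    trace = vals.sum(axis=-1)
    if energy_floor is None:
        energy_floor = 1e-6 * float(trace.max()) if trace.max() > 0 else 0.0
    mean = trace / 3.0
    dev = vals - mean[..., None]
    norm = np.sqrt((vals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt((dev**2).sum(axis=-1)) / norm
    fa = np.where((trace < energy_floor) | (norm == 0), 0.0, fa)
    fa = np.clip(np.nan_to_num(fa, nan=0.0), 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = (vals[..., 1] + vals[..., 2]) / (2.0 * trace)
    radial = np.where((trace < energy_floor) | (trace == 0), 1.0 / 3.0, radial)
    radial = np.clip(np.nan_to_num(radial, nan=1.0 / 3.0), 0.0, 0.5)
    return FaResult(fa=fa, radial=radial, energy_floor=float(energy_floor))


# --------------------------------------------------------------------------
# volume fraction
# --------------------------------------------------------------------------

def volume_fraction(
    v: Union[GrayVolume, np.ndarray],
    voi: Optional[Voi],
    threshold: float,
    polarity: Literal["hypo", "hyper"] = "hypo",
) -> float:
    """Fraction of VOI voxels on the fiber side of a fixed gray cutoff.

    ``polarity`` names the fiber contrast: ``hypo`` counts voxels at or
    below the threshold (dark fibers, anionic stains), ``hyper`` counts
    voxels at or above it.  The volume must already be on a scale where a
    constant threshold is meaningful across datasets (reference-matched
    16-bit or the dimensionless normalized scale).
    """
    x = v.voxels if isinstance(v, GrayVolume) else np.asarray(v)
    if voi is not None:
        sel = voi.contains_mask(x.shape)
        vals = x[sel]
    else:
        vals = x.ravel()
    if vals.size == 0:
        raise ContractError("VOI selects no voxels")
    if polarity == "hypo":
        return float((vals <= threshold).mean())
    if polarity == "hyper":
        return float((vals >= threshold).mean())
    raise ContractError(f"unknown polarity {polarity!r}")


# --------------------------------------------------------------------------
# cylinder-correlation fiber detection
# --------------------------------------------------------------------------

def _sample_orientations(angular_step_deg: float) -> list[np.ndarray]:
    """Unit directions over the hemisphere at roughly the given step."""
    dirs = [np.array([1.0, 0.0, 0.0])]  # along z
    n_theta = max(1, int(round(90.0 / angular_step_deg)))
    for it in range(1, n_theta + 1):
        theta = math.radians(it * angular_step_deg)
        if theta > math.pi / 2 + 1e-9:
            break
        n_phi = max(1, int(round(360.0 * math.sin(theta) / angular_step_deg)))
        for ip in range(n_phi):
            phi = 2 * math.pi * ip / n_phi
            d = np.array(
                [
                    math.cos(theta),
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi),
                ]
            )
            # hemisphere: keep one of each antipodal pair
            if d[0] < -1e-12:
                continue
            dirs.append(d)
    return dirs


def _cylinder_template(radius: float, length: float, direction: np.ndarray) -> np.ndarray:
    """Binary voxelized cylinder along ``direction`` centred in a cube."""
    half = int(math.ceil(max(length / 2.0, radius))) + 1
    side = 2 * half + 1
    g = np.mgrid[-half : half + 1, -half : half + 1, -half : half + 1].astype(float)
    coords = g.reshape(3, -1)
    axial = direction @ coords
    radial2 = (coords**2).sum(axis=0) - axial**2
    inside = (np.abs(axial) <= length / 2.0) & (radial2 <= radius**2)
    return inside.reshape(side, side, side)


def detect_fibers(
    v: Union[GrayVolume, np.ndarray],
    voi: Optional[Voi] = None,
    radii: Sequence[float] = (2.0,),
    length: float = 9.0,
    angular_step_deg: float = 30.0,
    polarity: Literal["hypo", "hyper"] = "hypo",
    cutoff: float = 0.5,
    orientations: Optional[Sequence[Sequence[float]]] = None,
) -> Tuple[Mask, np.ndarray]:
    """Detect tubular structures by oriented cylinder correlation.

    For every sampled orientation and template radius, the zero-mean
    cylinder template is cross-correlated with the volume and normalized
    by the local window standard deviation, giving a correlation in
    [-1, 1].  The per-voxel maximum over templates is the correlation
    map.  Because the correlation peaks on the cylinder axis and decays
    radially, the object mask is reconstructed by stamping the
    best-matching template's footprint at every above-``cutoff`` voxel,
    so a detected tube is covered across its full cross-section.  For
    hypointense fibers the template sign is flipped so that dark tubes
    score positively.

    Returns the detection mask (restricted to the VOI if one is given)
    and the correlation map.  Template radii and lengths are in voxels
    and must satisfy radius >= 1, length >= 3.
    """
    x = v.voxels if isinstance(v, GrayVolume) else np.asarray(v)
    x = x.astype(np.float64)
    if any(r < 1 for r in radii):
        raise ContractError("template radii must be >= 1 voxel")
    if length < 3:
        raise ContractError("template length must be >= 3 voxels")
    if orientations is not None:
        dirs = [np.asarray(d, float) / np.linalg.norm(d) for d in orientations]
    else:
        dirs = _sample_orientations(angular_step_deg)

    voi_sel = None
    if voi is not None:
        voi_sel = voi.contains_mask(x.shape)
        _, extent = voi.bounding_box()
    else:
        extent = x.shape

    best = np.full(x.shape, -np.inf)
    best_idx = np.zeros(x.shape, dtype=np.int16)
    templates = []
    x2 = x * x
    for ti, (radius, d) in enumerate(itertools.product(radii, dirs)):
        tpl = _cylinder_template(radius, length, d)
        templates.append(tpl)
        if any(t > e for t, e in zip(tpl.shape, extent)):
            raise ContractError(
                f"template {tpl.shape} larger than VOI extent {tuple(extent)}"
            )
        t0 = tpl.astype(np.float64) - tpl.mean()
        nrm = np.linalg.norm(t0)
        if nrm == 0:
            continue
        t0 /= nrm
        if polarity == "hypo":
            t0 = -t0
        flip = tuple(slice(None, None, -1) for _ in range(3))
        num = fftconvolve(x, t0[flip], mode="same")
        ones = np.ones_like(t0)
        n = t0.size
        s1 = fftconvolve(x, ones[flip], mode="same")
        s2 = fftconvolve(x2, ones[flip], mode="same")
        var = np.clip(s2 - s1 * s1 / n, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = num / np.sqrt(var)
        ncc = np.nan_to_num(ncc, nan=0.0, posinf=0.0, neginf=0.0)
        improved = ncc > best
        best_idx[improved] = ti
        np.maximum(best, ncc, out=best)
    best = np.clip(best, -1.0, 1.0)
    axis_hits = best >= cutoff
    mask = np.zeros(x.shape, dtype=bool)
    for ti, tpl in enumerate(templates):
        sel = axis_hits & (best_idx == ti)
        if sel.any():
            mask |= ndimage.binary_dilation(sel, structure=tpl)
    if voi_sel is not None:
        mask &= voi_sel
    return (
        Mask(mask, provenance={"cutoff": cutoff, "polarity": polarity, "radii": tuple(radii)}),
        best,
    )


# --------------------------------------------------------------------------
# labeling and thickness
# --------------------------------------------------------------------------

@dataclass
class FiberLabels:
    """Instance labels of individual fiber bundles (background = 0)."""

    labels: np.ndarray
    voxel_counts: Dict[int, int]

    @property
    def n_labels(self) -> int:
        return len(self.voxel_counts)


def label_fibers(
    detection: Mask,
    correlation: np.ndarray,
    min_separation: int = 2,
    h: float = 0.1,
) -> FiberLabels:
    """Split a fiber detection mask into individual bundles.

    Markers are the regional maxima of the correlation map inside the
    mask, extracted with an h-maxima transform so that noise ripples
    shallower than ``h`` along one bundle's correlation ridge do not
    fragment it; marker regions closer than ``min_separation`` voxels
    are merged.  A watershed of the inverted correlation, restricted to
    the mask, then assigns every mask voxel to one marker.  The whole
    procedure is deterministic.  An empty mask yields zero labels, not
    an error.
    """
    mask = detection.data
    if not mask.any():
        return FiberLabels(np.zeros(mask.shape, dtype=np.int32), {})
    corr = np.asarray(correlation, dtype=np.float64)
    if corr.shape != mask.shape:
        raise ContractError("correlation map shape differs from mask shape")
    floor_val = corr.min() - 1.0
    inside = np.where(mask, corr, floor_val)
    hmax = h_maxima(inside, h) > 0
    hmax &= mask
    if not hmax.any():
        hmax = mask & (inside >= np.max(inside) - 1e-12)
    if min_separation > 1:
        merged = ndimage.binary_dilation(hmax, structure=_ball(min_separation))
    else:
        merged = hmax
    marker_lbl, _ = ndimage.label(merged, structure=np.ones((3, 3, 3), bool))
    markers = np.where(hmax, marker_lbl, 0).astype(np.int32)
    lab = watershed(-corr, markers=markers, mask=mask)
    counts = {
        int(i): int(c) for i, c in enumerate(np.bincount(lab.ravel())) if i > 0 and c > 0
    }
    return FiberLabels(lab.astype(np.int32), counts)


def _ball(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    d2 = (g**2).sum(axis=0)
    return (d2 <= radius**2 + 1e-9).astype(bool)


def local_thickness(mask: np.ndarray) -> np.ndarray:
    """Local thickness map: diameter of the largest inscribed sphere.

    For every foreground voxel x, the local thickness is
    ``2 * max{ EDT(c) : c foreground, ||x - c|| <= EDT(c) }`` — twice the
    radius of the largest EDT-sphere that covers x while staying inside
    the object.  Computed by sweeping EDT radii in descending order and
    dilating each radius shell by a ball of that radius.
    """
    mask = np.asarray(mask, bool)
    lt = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return lt
    edt = ndimage.distance_transform_edt(mask)
    radii = np.unique(edt[mask])[::-1]
    for r in radii:
        if r <= 0:
            continue
        seeds = edt >= r - 1e-12
        cover = ndimage.binary_dilation(seeds, structure=_ball(r)) & mask
        lt = np.where(cover & (lt == 0), 2.0 * r, lt)
    return lt


@dataclass
class ThicknessReport:
    """Per-bundle mean local thickness and the median across bundles."""

    per_label_um: Dict[int, float]
    median_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.per_label_um), "thickness_um": list(self.per_label_um.values())}
        )


def fiber_thickness(labels: FiberLabels, voxel_size_um: float) -> ThicknessReport:
    """Thickness per fiber bundle from the local-thickness map.

    The local-thickness map is computed over the union of all labels (so
    touching bundles do not truncate each other's inscribed spheres),
    then averaged per label and converted to micrometres.
    """
    if labels.n_labels == 0:
        raise ContractError("no labels to measure")
    if not voxel_size_um > 0:
        raise ContractError("voxel_size_um must be positive")
    fg = labels.labels > 0
    lt = local_thickness(fg)
    per = {}
    for lab in labels.voxel_counts:
        sel = labels.labels == lab
        per[lab] = float(lt[sel].mean() * voxel_size_um)
    return ThicknessReport(per, float(np.median(list(per.values()))))


# --------------------------------------------------------------------------
# regional gray-value report
# --------------------------------------------------------------------------

@dataclass
class RegionGray:
    label: str
    normalized: float
    mean_gray: float
    n: int
    slices: Optional[Tuple[int, int]]
    pct_change: Optional[float] = None


@dataclass
class GrayValueReport:
    """Normalized gray values per named anatomical region.

    The canonical use is the four corpus-callosum positions
    (caudal-medial, caudal-lateral, rostral-medial, rostral-lateral)
    measured over a 50-slice slab; any named VOI set works.
    """

    entries: Dict[str, RegionGray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries.values():
            rows.append(
                {
                    "region": e.label,
                    "normalized_gray": e.normalized,
                    "mean_gray": e.mean_gray,
                    "n_voxels": e.n,
                    "pct_change": e.pct_change,
                }
            )
        return pd.DataFrame(rows)


def regional_gray_report(
    v: GrayVolume,
    refs: ReferenceGrayValues,
    regions: Dict[str, Voi],
    baseline: Optional[GrayValueReport] = None,
) -> GrayValueReport:
    """Normalized mean gray per named region, optionally vs a baseline.

    Each region's mean 16-bit gray is put on the tube/bead scale; when a
    baseline report is given (e.g. the healthy dataset), the percent
    change ``(g - g_base) / g_base * 100`` is attached per region, the
    proxy used to express regional demyelination.
    """
    if not regions:
        raise ContractError("no regions given")
    entries: Dict[str, RegionGray] = {}
    for name, voi in regions.items():
        sel = voi.contains_mask(v.shape)
        vals = v.voxels[sel].astype(np.float64)
        if vals.size == 0:
            raise ContractError(f"region {name!r} selects no voxels")
        g = normalized_gray(float(vals.mean()), refs, label=name)
        pct = None
        if baseline is not None:
            if name not in baseline.entries:
                raise ContractError(f"region {name!r} missing from baseline report")
            g0 = baseline.entries[name].normalized
            if g0 == 0:
                raise ContractError(f"baseline normalized gray of {name!r} is 0")
            pct = (g.value - g0) / g0 * 100.0
        entries[name] = RegionGray(
            label=name,
            normalized=g.value,
            mean_gray=float(vals.mean()),
            n=int(vals.size),
            slices=voi.slices,
            pct_change=pct,
        )
    return GrayValueReport(entries)
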