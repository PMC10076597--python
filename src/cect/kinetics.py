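"""Staining-front kinetics: segmentation, sphere approximation, decay fit.

When a fixed hemisphere is immersed in a contrast-enhancing staining agent
(CESA), the stain diffuses inward and a bright shell advances towards the
core.  The specimen is approximated as a sphere so that the penetration
depth can be inferred from two measured volumes:

    R_e = (3 V_e / 4 pi)^(1/3)     radius of the entire tissue sphere
    r_u = (3 V_u / 4 pi)^(1/3)     radius of the unstained core sphere
    r_p = R_e - r_u                depth of the penetration front

The depth over time follows a saturating exponential

    r_p(t) = R_e * (1 - exp(-k t))

whose asymptote R_e and rate k are fitted by bounded nonlinear least
squares.  Total-volume tracking over the staining period quantifies
swelling or shrinkage induced by the staining solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .errors import ContractError, SegmentationError
from .volume import GrayVolume, Mask, Voi

__all__ = [
    "StainThreshold",
    "SphericalKinetics",
    "DecayFit",
    "VolumeSeries",
    "segment_tissue",
    "measure_volume",
    "derive_stain_threshold",
    "segment_stained",
    "segment_unstained_core",
    "spherical_kinetics",
    "fit_penetration_decay",
    "volume_change_series",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class StainThreshold:
    """Gray cutoff above which tissue counts as stained.

    Derived from the least-attenuating tissue at the final time point,
    when staining is complete; ``percentile`` records the robustness
    margin used instead of the strict minimum.
    """

    value: float
    percentile: float
    source: str = "final-time-point"


@dataclass(frozen=True)
class SphericalKinetics:
    """Sphere-approximation quantities for one time point."""

    t_days: float
    v_entire_mm3: float
    v_unstained_mm3: float
    r_entire_mm: float
    r_unstained_mm: float
    penetration_depth_mm: float


@dataclass(frozen=True)
class DecayFit:
    """Fitted r_p(t) = R_e (1 - exp(-k t)) parameters."""

    r_entire_mm: float
    rate_per_day: float
    rss: float
    converged: bool

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.r_entire_mm * (1.0 - np.exp(-self.rate_per_day * np.asarray(t)))


@dataclass(frozen=True)
class VolumeSeries:
    """Total tissue volume per time point and percent change vs the first."""

    t_days: Tuple[float, ...]
    volumes_mm3: Tuple[float, ...]
    relative_change_pct: Tuple[float, ...]


def segment_tissue(
    v: GrayVolume,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: Optional[float] = None,
    exclude_vois: Sequence[Voi] = (),
) -> Mask:
    """Binarize the total tissue (hemisphere) volume.

    Thresholding (Otsu or a fixed cutoff) is followed by keeping the
    largest 26-connected component and filling internal holes — an
    automated stand-in for interactive lasso/brush editing, chosen so the
    result is reproducible.  Reference-material VOIs can be excluded so
    the bead or tube never joins the tissue component.
    """
    if method == "fixed":
        if threshold is None:
            raise ContractError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if v.voxels.min() == v.voxels.max():
            raise SegmentationError("constant volume: Otsu threshold undefined")
        thr = float(threshold_otsu(v.voxels))
    else:
        raise ContractError(f"unknown method {method!r}")
    fg = v.voxels >= thr
    for voi in exclude_vois:
        fg &= ~voi.contains_mask(v.shape)
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(counts.argmax())
    mask = labels == keep
    mask = ndimage.binary_fill_holes(mask)  # 6-connected background
    return Mask(
        mask,
        provenance={
            "threshold": thr,
            "method": method,
            "postprocessing": "largest-component-26 + fill-holes-6",
        },
    )


def measure_volume(m: Mask, voxel_size_um: float) -> float:
    """Mask volume in mm^3: voxel count times the voxel volume."""
    if not voxel_size_um > 0:
        raise ContractError("voxel_size_um must be positive")
    return m.voxel_count * (voxel_size_um / 1000.0) ** 3


def derive_stain_threshold(
    v_final: GrayVolume, tissue: Mask, percentile: float = 1.0
) -> StainThreshold:
    """Stain cutoff from the fully stained end point.

    Once no further gray change occurs between time points, every tissue
    voxel is stained, so a low percentile of the tissue grays bounds the
    least-attenuating stained tissue from below.  ``percentile=0`` gives
    the strict minimum; the default 1 tolerates noise outliers.
    """
    if tissue.shape != v_final.shape:
        raise ContractError("tissue mask shape differs from volume shape")
    vals = v_final.voxels[tissue.data]
    if vals.size == 0:
        raise ContractError("tissue mask is empty")
    if not 0 <= percentile <= 100:
        raise ContractError("percentile must lie in [0, 100]")
    thr = float(np.percentile(vals, percentile))
    return StainThreshold(thr, percentile)


def segment_stained(v: GrayVolume, tissue: Mask, thr: StainThreshold) -> Mask:
    """Stained tissue: tissue voxels at or above the stain cutoff."""
    if tissue.shape != v.shape:
        raise ContractError("tissue mask shape differs from volume shape")
    stained = tissue.data & (v.voxels >= thr.value)
    return Mask(stained, provenance={"threshold": thr.value, "parent": "tissue"})


def segment_unstained_core(v: GrayVolume, tissue: Mask, thr: StainThreshold) -> Mask:
    """Unstained core: sub-threshold tissue, cleaned to one solid region.

    Thresholding alone leaves a salt of isolated sub-threshold voxels
    wherever the noise tail of the stained gray crosses the cutoff; the
    physical unstained region is a single connected core, so only the
    largest 26-connected component is kept and its internal holes are
    filled — the automated counterpart of the interactive speckle
    removal used in manual segmentation.  An empty core (fully stained
    specimen) is a valid result, not an error.
    """
    if tissue.shape != v.shape:
        raise ContractError("tissue mask shape differs from volume shape")
    raw = tissue.data & (v.voxels < thr.value)
    if not raw.any():
        return Mask(raw, provenance={"threshold": thr.value, "empty": True})
    labels, _ = ndimage.label(raw, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    core = labels == int(counts.argmax())
    core = ndimage.binary_fill_holes(core)
    return Mask(
        core,
        provenance={
            "threshold": thr.value,
            "postprocessing": "largest-component-26 + fill-holes-6",
        },
    )


def spherical_kinetics(v_entire_mm3: float, v_unstained_mm3: float, t_days: float) -> SphericalKinetics:
    """Sphere-equivalent radii and penetration depth from two volumes."""
    if not v_entire_mm3 > 0:
        raise ContractError("entire volume must be positive")
    if not 0 <= v_unstained_mm3 <= v_entire_mm3:
        raise ContractError("unstained volume must lie in [0, entire volume]")
    r_e = (3.0 * v_entire_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_u = (3.0 * v_unstained_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return SphericalKinetics(
        t_days=t_days,
        v_entire_mm3=v_entire_mm3,
        v_unstained_mm3=v_unstained_mm3,
        r_entire_mm=r_e,
        r_unstained_mm=r_u,
        penetration_depth_mm=r_e - r_u,
    )


_K_MAX = 1e3  # per day; effectively instantaneous full staining


def fit_penetration_decay(
    points: Sequence[Tuple[float, float]],
    weights: Optional[Sequence[float]] = None,
) -> DecayFit:
    """Least-squares fit of r_p(t) = R_e (1 - exp(-k t)).

    Both parameters are constrained positive.  Initialisation uses the
    largest observed depth for R_e and 1/median(t) for k.  A fit that
    fails, pins k at its bound, or leaves k unidentified — the curve is
    already saturated to within 1e-6 at the earliest observation, as
    happens when every depth is equal — is returned with
    ``converged=False`` rather than raising, so a study over many
    specimens never aborts on one degenerate series.
    """
    pts = [(float(t), float(r)) for t, r in points]
    if len({t for t, _ in pts}) < 3:
        raise ContractError("need at least 3 distinct time points")
    if any(t <= 0 for t, _ in pts):
        raise ContractError("time points must be positive")
    if any(r < 0 for _, r in pts):
        raise ContractError("penetration depths must be non-negative")
    t = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    w = np.ones_like(t) if weights is None else np.sqrt(np.asarray(weights, float))

    def resid(theta: np.ndarray) -> np.ndarray:
        re_, k = theta
        return w * (re_ * (1.0 - np.exp(-k * t)) - r)

    r0 = max(r.max(), 1e-6)
    k0 = 1.0 / np.median(t)
    try:
        res = optimize.least_squares(
            resid,
            x0=[r0, k0],
            bounds=([1e-12, 1e-12], [np.inf, _K_MAX]),
        )
        re_hat, k_hat = res.x
        rss = float(2 * res.cost)
        identified = k_hat * t.min() < -math.log(1e-6)
        converged = bool(res.success) and k_hat < _K_MAX * (1 - 1e-9) and identified
    except Exception:
        re_hat, k_hat, rss, converged = r0, k0, float("nan"), False
    return DecayFit(float(re_hat), float(k_hat), rss, converged)


def volume_change_series(volumes: Sequence[Tuple[float, float]]) -> VolumeSeries:
    """Percent total-volume change relative to the first time point."""
    if len(volumes) < 2:
        raise ContractError("need at least 2 time points")
    t = tuple(float(a) for a, _ in volumes)
    v = tuple(float(b) for _, b in volumes)
    if any(x <= 0 for x in v):
        raise ContractError("volumes must be positive")
    rel = tuple((x / v[0] - 1.0) * 100.0 for x in v)
    return VolumeSeries(t_days=t, volumes_mm3=v, relative_change_pct=rel)
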