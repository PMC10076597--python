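"""Contrast-to-noise ratio between regions and Otsu binarization.

The contrast-to-noise ratio (CNR) between two regions of interest — here
typically white matter (corpus callosum) against gray matter (inner
cerebral cortex) — is

    CNR = |mu_1 - mu_2| / ((sigma_1 + sigma_2) / 2)

computed on the 16-bit gray values.  It is symmetric, dimensionless and
invariant under joint affine rescaling of the grays, which makes it
comparable across normalized datasets.  Higher CNR means the two tissues
separate more cleanly under automatic thresholding, which the Otsu
binarization here makes concrete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ContractError
from .volume import GrayVolume, Mask, Voi

__all__ = ["RoiStats", "roi_stats", "cnr", "otsu_binarize", "otsu_threshold_256"]


@dataclass(frozen=True)
class RoiStats:
    """Mean/SD/count of gray values over a region of interest.

    The SD is the population standard deviation (divide by n); with ROI
    sizes in the thousands of voxels the distinction from the sample SD
    is immaterial, but the choice is fixed for reproducibility.
    """

    mean: float
    sd: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ContractError("ROI voxel count must be positive")
        if self.sd < 0:
            raise ContractError("SD cannot be negative")


def roi_stats(v: GrayVolume, roi: Union[Voi, Mask], label: str = "") -> RoiStats:
    """Gray-value statistics over a VOI or an explicit mask."""
    if isinstance(roi, Voi):
        sel = roi.contains_mask(v.shape)
    else:
        if roi.shape != v.shape:
            raise ContractError("mask shape differs from volume shape")
        sel = roi.data
    vals = v.voxels[sel].astype(np.float64)
    if vals.size == 0:
        raise ContractError("ROI selects no voxels")
    return RoiStats(float(vals.mean()), float(vals.std()), int(vals.size), label)


def cnr(a: RoiStats, b: RoiStats) -> float:
    """Contrast-to-noise ratio between two regions.

    Degenerate noise-free inputs: if both SDs are zero the ratio is 0 for
    equal means and +inf for different means (perfectly separable).
    """
    noise = (a.sd + b.sd) / 2.0
    diff = abs(a.mean - b.mean)
    if noise == 0:
        return 0.0 if diff == 0 else math.inf
    return diff / noise


def otsu_threshold_256(values: np.ndarray) -> float:
    """Otsu's threshold on a 256-bin histogram of the values.

    Exhaustively maximises the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2`` over all 256 bin boundaries and returns
    the gray value at the chosen boundary (lower edge of the first
    foreground bin).  Ties take the lowest boundary.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ContractError("constant region: Otsu threshold undefined")
    hist, edges = np.histogram(values, bins=256, range=(lo, hi))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        between = np.where(
            (w0 > 0) & (w1 > 0), (mu_t * w0 - mu) ** 2 / (w0 * w1), -np.inf
        )
    k = int(np.argmax(between[:-1]))  # boundary after bin k
    return float(edges[k + 1])


def otsu_binarize(v: GrayVolume, voi: Voi) -> Mask:
    """Binarize a VOI at the Otsu threshold of its 256-bin histogram.

    Foreground is ``gray >= threshold``; voxels outside the VOI are
    background.  Requires at least two distinct gray values in the VOI.
    """
    sel = voi.contains_mask(v.shape)
    vals = v.voxels[sel]
    if vals.size == 0:
        raise ContractError("VOI selects no voxels")
    thr = otsu_threshold_256(vals)
    out = np.zeros(v.shape, dtype=bool)
    out[sel] = v.voxels[sel] >= thr
    return Mask(out, provenance={"threshold": thr, "method": "otsu-256"})
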