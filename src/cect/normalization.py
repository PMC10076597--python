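"""Gray-value windowing and reference-based normalization.

Reconstructed attenuation volumes arrive as 16-bit gray values whose
absolute scale drifts between acquisitions.  Two remedies are provided:

* **Histogram windowing** — a linear map of a chosen gray interval onto the
  8-bit range, used when converting 16-bit TIFF stacks to 8-bit BMP stacks
  for visualisation and lightweight processing.
* **Reference normalization** — every dataset carries reference materials
  in the field of view (a ceramic Al2O3 bead, the polypropylene sample
  tube, and air).  Tissue gray values are expressed on a dimensionless
  scale anchored to the tube (0) and the bead (1):

      g_X = (G_X - G_E) / (G_B - G_E)

  where G_X, G_E and G_B are the mean grays of the tissue region, the tube
  and the bead.  Whole datasets can also be rescaled so their tube/air
  grays match those of a designated anchor dataset, making raw 16-bit
  values comparable across scans of the same staining agent.

Quantitative analyses run on the 16-bit data; the 8-bit conversion is for
export only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ContractError, DegenerateWindowError
from .volume import GrayVolume, Voi

__all__ = [
    "WindowSpec",
    "ReferenceGrayValues",
    "NormalizedGrayValue",
    "auto_window",
    "apply_window",
    "normalize_to_references",
    "normalized_gray",
    "measure_reference_grays",
]


@dataclass(frozen=True)
class WindowSpec:
    """Gray interval mapped onto the full target range.

    ``low`` maps to 0 and ``high`` to the maximum of the target bit depth;
    values outside are clipped.  ``source`` records how the window was
    derived (e.g. ``"auto-percentile"``).
    """

    low: float
    high: float
    source: str = "manual"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise DegenerateWindowError(
                f"window low ({self.low}) must be < high ({self.high})"
            )


@dataclass(frozen=True)
class RefStat:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ReferenceGrayValues:
    """Mean gray values of the in-scene reference materials.

    ``bead`` (G_B, ceramic Al2O3, brightest), ``tube`` (G_E, Eppendorf
    polypropylene) and optionally ``air`` (G_air, darkest).  Ordering
    G_B > G_E >= G_air is enforced: a violation means the VOIs were
    misplaced.
    """

    bead: RefStat
    tube: RefStat
    air: Optional[RefStat] = None

    def __post_init__(self) -> None:
        if not self.bead.mean > self.tube.mean:
            raise ContractError("bead gray must exceed tube gray")
        if self.air is not None and self.tube.mean < self.air.mean:
            raise ContractError("tube gray must be >= air gray")
        for r in (self.bead, self.tube) + (() if self.air is None else (self.air,)):
            if r.n <= 0:
                raise ContractError("reference voxel counts must be positive")


@dataclass(frozen=True)
class NormalizedGrayValue:
    """Dimensionless gray on the tube(0)-bead(1) scale, with its region label."""

    value: float
    label: str = ""


def auto_window(v: GrayVolume, p_low: float = 0.1, p_high: float = 99.9) -> WindowSpec:
    """Percentile-based automatic window of the volume histogram.

    Percentile windowing is robust to isolated hot pixels; ``(0, 100)``
    degenerates to the plain min/max window.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ContractError("need 0 <= p_low < p_high <= 100")
    low, high = np.percentile(v.voxels, [p_low, p_high])
    if low == high:
        raise DegenerateWindowError(
            "volume histogram is degenerate over the requested percentiles"
        )
    return WindowSpec(float(low), float(high), source="auto-percentile")


def apply_window(v: GrayVolume, w: WindowSpec) -> GrayVolume:
    """Linear 16-to-8-bit conversion: clip to the window, map onto 0..255.

    Rounding is half-up, so the exact midpoint of the window lands on 128.
    The map is monotone non-decreasing in the input gray value.
    """
    x = v.voxels.astype(np.float64)
    scaled = (x - w.low) / (w.high - w.low) * 255.0
    out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    out = np.clip(out, 0, 255).astype(np.uint8)
    return GrayVolume(out, v.voxel_size_um)


def measure_reference_grays(
    v: GrayVolume,
    bead_voi: Voi,
    tube_voi: Voi,
    air_voi: Optional[Voi] = None,
) -> ReferenceGrayValues:
    """Mean/SD/count of each reference region.

    The VOIs must be pairwise disjoint and inside the lattice; overlap
    would mix materials and bias the anchors.
    """
    vois = [("bead", bead_voi), ("tube", tube_voi)]
    if air_voi is not None:
        vois.append(("air", air_voi))
    masks = {}
    for name, voi in vois:
        m = voi.contains_mask(v.shape)
        if not m.any():
            raise ContractError(f"{name} VOI selects no voxels")
        masks[name] = m
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (masks[a] & masks[b]).any():
                raise ContractError(f"reference VOIs {a} and {b} overlap")

    def stat(m: np.ndarray) -> RefStat:
        vals = v.voxels[m].astype(np.float64)
        return RefStat(float(vals.mean()), float(vals.std()), int(vals.size))

    return ReferenceGrayValues(
        bead=stat(masks["bead"]),
        tube=stat(masks["tube"]),
        air=stat(masks["air"]) if air_voi is not None else None,
    )


def normalized_gray(
    g_x: float, refs: ReferenceGrayValues, label: str = ""
) -> NormalizedGrayValue:
    """Tube/bead-anchored normalized gray: (G_X - G_E) / (G_B - G_E).

    Equal to 0 at the tube gray and 1 at the bead gray; invariant under
    any affine rescaling applied jointly to the tissue and both anchors.
    """
    denom = refs.bead.mean - refs.tube.mean
    if denom == 0:
        raise DegenerateWindowError("bead and tube grays coincide")
    return NormalizedGrayValue((g_x - refs.tube.mean) / denom, label=label)


def normalize_to_references(
    volumes: Sequence[GrayVolume],
    refs: Sequence[ReferenceGrayValues],
    anchor_index: int = 0,
) -> list[GrayVolume]:
    """Rescale datasets so their reference grays match an anchor dataset.

    Each volume is mapped by the unique affine transform taking its own
    (tube, air) gray pair onto the anchor's; if air was not measured, the
    (bead, tube) pair is used instead.  The anchor is returned unchanged.
    Output is clipped and rounded back to the input bit depth.
    """
    if len(volumes) != len(refs):
        raise ContractError("need one ReferenceGrayValues per volume")
    if not 0 <= anchor_index < len(volumes):
        raise ContractError("anchor_index out of range")

    def pair(r: ReferenceGrayValues) -> tuple[float, float]:
        if r.air is not None:
            return r.tube.mean, r.air.mean
        return r.bead.mean, r.tube.mean

    hi_a, lo_a = pair(refs[anchor_index])
    out: list[GrayVolume] = []
    info_max = {8: 255, 16: 65535}
    for i, (v, r) in enumerate(zip(volumes, refs)):
        if i == anchor_index:
            out.append(v)
            continue
        hi, lo = pair(r)
        if hi == lo:
            raise DegenerateWindowError(
                f"volume {i}: reference grays coincide ({hi})"
            )
        scale = (hi_a - lo_a) / (hi - lo)
        x = (v.voxels.astype(np.float64) - lo) * scale + lo_a
        cap = info_max[v.bit_depth]
        x = np.clip(np.floor(x + 0.5), 0, cap).astype(v.voxels.dtype)
        out.append(GrayVolume(x, v.voxel_size_um))
    return out
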