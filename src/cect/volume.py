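"""Voxel-grid data model and slice-stack I/O.

A reconstructed microCT dataset is a 3D lattice of scalar gray values on an
isotropic grid, stored on disk as a stack of 2D slice images (16-bit TIFF
from the reconstruction, or 8-bit BMP after windowing).  The gray-value
convention follows attenuation reconstructions: 0 is no attenuation (air)
and the dtype maximum is the strongest attenuator in the field of view.

Axis convention is ``(z, y, x)``: axis 0 indexes slices, axes 1-2 are image
rows and columns.  After reorientation the coronal anatomical plane is the
xy-plane.  All VOIs are half-open and 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence, Tuple

import numpy as np
import tifffile
from imageio import v3 as iio
from scipy import ndimage

from .errors import ContractError, FormatError, GeometryError

__all__ = [
    "GrayVolume",
    "Voi",
    "Mask",
    "read_volume",
    "write_volume",
    "extract_voi",
    "voi_extent_mm",
    "spatial_resolution_bounds_um",
    "reorient",
]

_DTYPES = {8: np.uint8, 16: np.uint16}
_SIDECAR_NAME = "volume_meta.json"


@dataclass
class GrayVolume:
    """A 3D scalar attenuation lattice with isotropic voxel size.

    Parameters
    ----------
    voxels
        3D array, ``uint8`` or ``uint16``, indexed ``(z, y, x)``.
    voxel_size_um
        Isotropic voxel edge length in micrometres; must be positive.
    """

    voxels: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ContractError("voxels must be a non-empty 3D array")
        if self.voxels.dtype == np.uint8:
            self._bit_depth = 8
        elif self.voxels.dtype == np.uint16:
            self._bit_depth = 16
        else:
            raise ContractError(
                f"unsupported dtype {self.voxels.dtype}; use uint8 or uint16"
            )
        if not self.voxel_size_um > 0:
            raise ContractError("voxel_size_um must be positive")

    @property
    def bit_depth(self) -> int:
        """8 or 16, inferred from the array dtype."""
        return self._bit_depth

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / 1000.0) ** 3

    def copy(self) -> "GrayVolume":
        return GrayVolume(self.voxels.copy(), self.voxel_size_um)

    def with_voxels(self, voxels: np.ndarray) -> "GrayVolume":
        """New volume sharing this grid's voxel size."""
        return GrayVolume(voxels, self.voxel_size_um)


@dataclass(frozen=True)
class Voi:
    """A volume of interest: an axis-aligned box or a sphere.

    Boxes are given by a 0-based ``origin`` (z, y, x) and positive
    ``extent`` per axis; the covered index range is half-open.  Spheres are
    given by a ``center`` voxel and a ``radius`` in voxels.  An optional
    half-open ``slices`` interval restricts either shape to a slab.
    """

    kind: Literal["box", "sphere"]
    origin: Optional[Tuple[int, int, int]] = None
    extent: Optional[Tuple[int, int, int]] = None
    center: Optional[Tuple[float, float, float]] = None
    radius: Optional[float] = None
    slices: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind == "box":
            if self.origin is None or self.extent is None:
                raise ContractError("box VOI requires origin and extent")
            if any(e <= 0 for e in self.extent):
                raise ContractError("box extents must be positive")
        elif self.kind == "sphere":
            if self.center is None or self.radius is None:
                raise ContractError("sphere VOI requires center and radius")
            if self.radius <= 0:
                raise ContractError("sphere radius must be positive")
        else:
            raise ContractError(f"unknown VOI kind {self.kind!r}")
        if self.slices is not None and self.slices[0] >= self.slices[1]:
            raise ContractError("slice interval must be non-empty, half-open")

    @classmethod
    def box(
        cls,
        origin: Sequence[int],
        extent: Sequence[int],
        slices: Optional[Tuple[int, int]] = None,
    ) -> "Voi":
        return cls("box", origin=tuple(origin), extent=tuple(extent), slices=slices)

    @classmethod
    def sphere(
        cls,
        center: Sequence[float],
        radius: float,
        slices: Optional[Tuple[int, int]] = None,
    ) -> "Voi":
        return cls("sphere", center=tuple(center), radius=radius, slices=slices)

    def bounding_box(self) -> Tuple[Tuple[int, int, int], Tuple[int, int, int]]:
        """(origin, extent) of the tightest enclosing box."""
        if self.kind == "box":
            origin = list(self.origin)  # type: ignore[arg-type]
            stop = [o + e for o, e in zip(self.origin, self.extent)]  # type: ignore[arg-type]
        else:
            origin = [int(math.floor(c - self.radius)) for c in self.center]  # type: ignore[union-attr]
            stop = [int(math.ceil(c + self.radius)) + 1 for c in self.center]  # type: ignore[union-attr]
        if self.slices is not None:
            origin[0] = max(origin[0], self.slices[0])
            stop[0] = min(stop[0], self.slices[1])
        extent = [s - o for o, s in zip(origin, stop)]
        return tuple(origin), tuple(extent)  # type: ignore[return-value]

    def contains_mask(self, shape: Tuple[int, int, int]) -> np.ndarray:
        """Boolean lattice of the given shape selecting the VOI voxels."""
        out = np.zeros(shape, dtype=bool)
        origin, extent = self.bounding_box()
        sl = tuple(slice(o, o + e) for o, e in zip(origin, extent))
        if self.kind == "box":
            out[sl] = True
        else:
            zz, yy, xx = np.ogrid[sl]
            cz, cy, cx = self.center  # type: ignore[misc]
            dist2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            out[sl] = dist2 <= self.radius**2  # type: ignore[operator]
        return out


@dataclass
class Mask:
    """A binary lattice congruent with a :class:`GrayVolume`.

    ``provenance`` records how the mask was made (threshold value,
    post-processing steps) so reports stay auditable.
    """

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ContractError("mask must be 3D")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


def _iter_slice_files(directory: Path) -> Iterator[Path]:
    exts = {".tif", ".tiff", ".bmp", ".png"}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in exts and p.name != _SIDECAR_NAME:
            yield p


def read_volume(path: str | Path, voxel_size_um: Optional[float] = None) -> GrayVolume:
    """Read a slice stack (directory of slices or one multipage TIFF).

    Slice order — lexicographic file order within a directory, or page
    order in a multipage TIFF — defines the z axis.  Bit depth is inferred
    from the pixel dtype.  A ``volume_meta.json`` sidecar, if present next
    to the data, supplies ``voxel_size_um``; an explicit argument wins.

    Raises
    ------
    FormatError
        If slices disagree in shape or dtype, or the dtype is unsupported.
    ContractError
        If the directory holds no slice images and no voxel size is known.
    """
    path = Path(path)
    sidecar = None
    if path.is_dir():
        files = list(_iter_slice_files(path))
        if not files:
            raise ContractError(f"no slice images found in {path}")
        slices = [np.asarray(iio.imread(f)) for f in files]
        shapes = {s.shape for s in slices}
        dtypes = {s.dtype for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        if len(dtypes) != 1:
            raise FormatError(f"mixed slice dtypes in {path}: {dtypes}")
        data = np.stack(slices, axis=0)
        sidecar = path / _SIDECAR_NAME
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_name(_SIDECAR_NAME)
    if data.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"unsupported pixel dtype {data.dtype}")
    if voxel_size_um is None and sidecar is not None and sidecar.exists():
        voxel_size_um = float(json.loads(sidecar.read_text())["voxel_size_um"])
    if voxel_size_um is None:
        raise ContractError("voxel_size_um not given and no sidecar found")
    return GrayVolume(data, voxel_size_um)


def write_volume(
    v: GrayVolume, path: str | Path, format: Literal["tiff16", "bmp8"] = "tiff16"
) -> list[Path]:
    """Write one file per slice with zero-padded numeric names.

    ``bmp8`` requires an 8-bit volume: windowing to 8 bit is an explicit,
    separate step (see :mod:`cect.normalization`), never implicit here.
    A ``volume_meta.json`` sidecar records the voxel size and bit depth.
    """
    if format == "bmp8" and v.bit_depth != 8:
        raise ContractError(
            "bmp8 output requires an 8-bit volume; apply a window first"
        )
    if format == "tiff16" and v.bit_depth != 16:
        raise ContractError("tiff16 output requires a 16-bit volume")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ext = "tif" if format == "tiff16" else "bmp"
    width = max(4, len(str(v.shape[0] - 1)))
    written = []
    for i in range(v.shape[0]):
        f = path / f"slice_{i:0{width}d}.{ext}"
        if format == "tiff16":
            tifffile.imwrite(f, v.voxels[i])
        else:
            iio.imwrite(f, v.voxels[i])
        written.append(f)
    meta = {"voxel_size_um": v.voxel_size_um, "bit_depth": v.bit_depth}
    (path / _SIDECAR_NAME).write_text(json.dumps(meta))
    return written


def extract_voi(v: GrayVolume, voi: Voi) -> Tuple[GrayVolume, Optional[Mask]]:
    """Copy the sub-lattice covered by a VOI.

    Box VOIs return ``(sub_volume, None)``.  Sphere VOIs return the
    bounding box plus a congruent boolean mask selecting the in-sphere
    voxels of that box.
    """
    origin, extent = voi.bounding_box()
    stop = [o + e for o, e in zip(origin, extent)]
    if any(o < 0 for o in origin) or any(
        s > n for s, n in zip(stop, v.shape)
    ) or any(e <= 0 for e in extent):
        raise GeometryError(
            f"VOI bounding box {origin}+{extent} exceeds lattice {v.shape}"
        )
    sl = tuple(slice(o, s) for o, s in zip(origin, stop))
    sub = v.with_voxels(v.voxels[sl].copy())
    if voi.kind == "box":
        return sub, None
    zz, yy, xx = np.ogrid[sl]
    cz, cy, cx = voi.center  # type: ignore[misc]
    inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= voi.radius**2  # type: ignore[operator]
    return sub, Mask(inside, provenance={"voi": "sphere", "radius": voi.radius})


def spatial_resolution_bounds_um(
    voxel_size_um: float, factors: Tuple[float, float] = (2.0, 3.0)
) -> Tuple[float, float]:
    """Rule-of-thumb true spatial resolution for a reconstructed CT volume.

    The achievable spatial resolution is typically two to three times the
    voxel size, so a 6 um voxel grid resolves features no smaller than
    roughly 12-18 um.  Returns ``(lower, upper)`` in micrometres.
    """
    if not voxel_size_um > 0:
        raise ContractError("voxel_size_um must be positive")
    lo, hi = factors
    if not 0 < lo <= hi:
        raise ContractError("factors must be positive and ordered")
    return (lo * voxel_size_um, hi * voxel_size_um)


def voi_extent_mm(n_slices: int, voxel_size_um: float) -> float:
    """Physical slab extent in mm of ``n_slices`` at the given voxel size."""
    if n_slices < 1:
        raise ContractError("n_slices must be >= 1")
    if not voxel_size_um > 0:
        raise ContractError("voxel_size_um must be positive")
    return n_slices * voxel_size_um / 1000.0


def _axis_rotation(axis: int, deg: float) -> np.ndarray:
    """3x3 rotation of index vectors (z, y, x) about one array axis."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    other = [a for a in range(3) if a != axis]
    m = np.eye(3)
    m[other[0], other[0]] = c
    m[other[0], other[1]] = -s
    m[other[1], other[0]] = s
    m[other[1], other[1]] = c
    return m


def _rotation_matrix_zyx(euler_zyx_deg: Sequence[float]) -> np.ndarray:
    rz, ry, rx = euler_zyx_deg
    return _axis_rotation(0, rz) @ _axis_rotation(1, ry) @ _axis_rotation(2, rx)


def _is_right_angle_z(euler_zyx_deg: Sequence[float]) -> Optional[int]:
    """Quarter-turn count about z if the rotation is exactly that, else None."""
    rz, ry, rx = euler_zyx_deg
    if ry == 0 and rx == 0 and rz % 90 == 0:
        return int(rz // 90) % 4
    return None


def reorient(
    v: GrayVolume,
    euler_zyx_deg: Sequence[float],
    order: int = 1,
) -> GrayVolume:
    """Rotate a volume about its center, resampling on the same grid.

    The rotation is intrinsic Euler angles in degrees applied about the
    z, then y, then x axes (in array index convention).  Used to align the
    coronal anatomical plane with the xy-plane before regional analyses.
    Out-of-field voxels are filled with 0, the attenuation of air.

    ``order`` is the spline interpolation order (0 = nearest neighbour,
    1 = linear, default).  Exact quarter-turns about z in nearest mode are
    executed as voxel permutations, so they are lossless and composable.
    """
    if len(euler_zyx_deg) != 3:
        raise ContractError("expected three Euler angles (z, y, x) in degrees")
    q = _is_right_angle_z(euler_zyx_deg)
    if q is not None and order == 0:
        # exact permutation: np.rot90 in the (y, x) plane
        return v.with_voxels(np.ascontiguousarray(np.rot90(v.voxels, k=q, axes=(1, 2))))
    mat = _rotation_matrix_zyx(euler_zyx_deg)
    center = (np.asarray(v.shape) - 1) / 2.0
    # affine_transform maps output coords -> input coords: inverse rotation
    inv = mat.T
    offset = center - inv @ center
    out = ndimage.affine_transform(
        v.voxels.astype(np.float64),
        inv,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
    )
    info = np.iinfo(_DTYPES[v.bit_depth])
    out = np.clip(np.rint(out), info.min, info.max).astype(v.voxels.dtype)
    return v.with_voxels(out)
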