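"""Network input preparation: dose resampling, cropping and normalization.

The crop follows the clinical centering rules: left-right on the PTV53
centre of mass, cranio-caudally on the rectal centre of mass, and
anterior-posteriorly such that the entire rectum is inside the window.
Non-integer centres of mass are floored.  If the window extends past the
source grid it is zero-padded (with a logged warning).  Cropping never
discards rectum voxels; that is asserted on every call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import STRUCTURES, DoseGrid, GridError, StructureSet

log = logging.getLogger(__name__)

#: Fixed channel order of the network input.
CHANNEL_ORDER = STRUCTURES

#: Full-scale crop window as (X, Y, Z); stored arrays are (z, y, x).
FULL_SCALE_WINDOW_XYZ = (128, 128, 64)
DESK_SCALE_WINDOW_XYZ = (32, 32, 16)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationConstant:
    """Cohort-maximum dose used to map Gy to the network's unit scale."""

    max_dose_gy: float
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if not self.max_dose_gy > 0:
            raise PreprocessError("normalization constant must be strictly positive")

    @classmethod
    def from_cohort(cls, doses, cohort_id: str = "") -> "NormalizationConstant":
        m = max(float(d.dose_gy.max() if isinstance(d, DoseGrid) else np.max(d)) for d in doses)
        if m <= 0:
            raise PreprocessError("cohort maximum dose is not positive")
        return cls(m, cohort_id)


def normalize(dose, c: NormalizationConstant) -> np.ndarray:
    arr = dose.dose_gy if isinstance(dose, DoseGrid) else np.asarray(dose, dtype=np.float64)
    return arr / c.max_dose_gy


def denormalize(values: np.ndarray, c: NormalizationConstant) -> np.ndarray:
    return np.asarray(values, dtype=np.float64) * c.max_dose_gy


@dataclass
class ModelInputTensor:
    """Five binary channels (ptv68, ptv60, ptv53, rectum, bladder) on a crop.

    ``channels`` has shape ``(5, z, y, x)``; ``crop_offset`` locates the
    crop window in the source grid (``(z0, y0, x0)``, may be negative when
    zero-padding occurred).
    """

    channels: np.ndarray
    crop_offset: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.channels.ndim != 4 or self.channels.shape[0] != len(CHANNEL_ORDER):
            raise PreprocessError(
                f"channels must have shape (5, z, y, x), got {self.channels.shape}"
            )
        self.channels = self.channels.astype(bool)

    @property
    def window_zyx(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        z, y, x = self.window_zyx
        return (x, y, z)

    def mask(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_ORDER.index(name)]


def resample_dose(
    dose: DoseGrid,
    target_spacing_mm,
    target_shape=None,
) -> DoseGrid:
    """Resample a dose grid onto a new spacing with a third-order spline.

    The target grid shares the source origin.  Negative interpolation
    overshoot is clamped to zero.
    """
    spacing = tuple(float(s) for s in target_spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise PreprocessError("target spacing must be 3 strictly positive reals")
    if target_shape is None:
        target_shape = tuple(
            int(round(n * s_src / s_tgt))
            for n, s_src, s_tgt in zip(dose.shape, dose.spacing_mm, spacing)
        )
    target_shape = tuple(int(n) for n in target_shape)
    if any(n <= 0 for n in target_shape):
        raise PreprocessError("target shape must be positive")

    # physical coordinate of target voxel i is i * s_tgt -> source index i * s_tgt / s_src
    coords = np.meshgrid(
        *[
            np.arange(n) * s_tgt / s_src
            for n, s_tgt, s_src in zip(target_shape, spacing, dose.spacing_mm)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(dose.dose_gy, coords, order=3, mode="nearest")
    return DoseGrid(np.clip(out, 0.0, None), spacing, dose.origin_mm)


def _floor_com(com) -> int:
    return int(np.floor(com))


def _axis_window(centre: int, size: int, lo_req: int | None, hi_req: int | None, n_src: int, axis: str):
    """Window start for one axis: centred, shifted minimally to contain [lo, hi]."""
    start = centre - size // 2
    if lo_req is not None:
        extent = hi_req - lo_req + 1
        if extent > size:
            raise PreprocessError(
                f"rectum extent {extent} exceeds the {size}-voxel crop window on axis {axis}"
            )
        shifted = min(max(start, hi_req + 1 - size), lo_req)
        if shifted != start:
            log.debug("crop window shifted on axis %s to keep the rectum inside", axis)
        start = shifted
    return start


def crop_to_input(
    anatomy: StructureSet,
    dose: DoseGrid | None = None,
    window_xyz=DESK_SCALE_WINDOW_XYZ,
) -> tuple[ModelInputTensor, DoseGrid | None]:
    """Crop a five-structure set (and optionally its dose) to the network window."""
    missing = [s for s in CHANNEL_ORDER if s not in anatomy.masks]
    if missing:
        raise PreprocessError(f"anatomy is missing structures {missing} (select a boost first?)")
    if dose is not None and dose.shape != anatomy.shape:
        raise GridError("dose and anatomy are on different grids")

    wx, wy, wz = (int(v) for v in window_xyz)
    window = (wz, wy, wx)
    rectum = anatomy.masks["rectum"]
    ptv53 = anatomy.masks["ptv53"]
    rect_idx = np.nonzero(rectum)

    com_x = _floor_com(ndimage.center_of_mass(ptv53)[2])
    com_z = _floor_com(ndimage.center_of_mass(rectum)[0])
    com_y = _floor_com(ndimage.center_of_mass(rectum)[1])

    starts = []
    for axis, (centre, size, coords) in enumerate(
        [(com_z, wz, rect_idx[0]), (com_y, wy, rect_idx[1]), (com_x, wx, rect_idx[2])]
    ):
        starts.append(
            _axis_window(
                centre, size, int(coords.min()), int(coords.max()), anatomy.shape[axis], "zyx"[axis]
            )
        )
    z0, y0, x0 = starts

    def extract(volume, fill=0):
        out = np.full(window, fill, dtype=volume.dtype)
        src_lo = [max(0, s) for s in (z0, y0, x0)]
        src_hi = [min(n, s + w) for n, s, w in zip(volume.shape, (z0, y0, x0), window)]
        if any(lo >= hi for lo, hi in zip(src_lo, src_hi)):
            return out
        dst_lo = [lo - s for lo, s in zip(src_lo, (z0, y0, x0))]
        dst_hi = [hi - s for hi, s in zip(src_hi, (z0, y0, x0))]
        out[dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]] = volume[
            src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
        ]
        return out

    if any(s < 0 for s in (z0, y0, x0)) or any(
        s + w > n for s, w, n in zip((z0, y0, x0), window, anatomy.shape)
    ):
        log.warning("crop window extends past the source grid; zero-padding")

    channels = np.stack([extract(anatomy.masks[name]) for name in CHANNEL_ORDER])
    tensor = ModelInputTensor(
        channels=channels,
        crop_offset=(z0, y0, x0),
        spacing_mm=anatomy.spacing_mm,
        source_shape=anatomy.shape,
    )

    # hard guarantee: the crop never discards rectum voxels
    if int(tensor.mask("rectum").sum()) != int(rectum.sum()):
        raise AssertionError("crop dropped rectum voxels; this is a bug")

    cropped_dose = None
    if dose is not None:
        cropped_dose = DoseGrid(
            extract(dose.dose_gy),
            dose.spacing_mm,
            tuple(o + s * sp for o, s, sp in zip(dose.origin_mm, (z0, y0, x0), dose.spacing_mm)),
        )
    return tensor, cropped_dose


def paste_into_source(values: np.ndarray, tensor: ModelInputTensor, fill: float = 0.0) -> np.ndarray:
    """Inverse of the crop: place a window-shaped volume back at ``crop_offset``."""
    if values.shape != tensor.window_zyx:
        raise PreprocessError("volume shape does not match the crop window")
    out = np.full(tensor.source_shape, fill, dtype=np.float64)
    z0, y0, x0 = tensor.crop_offset
    src_lo = [max(0, -s) for s in (z0, y0, x0)]
    dst_lo = [max(0, s) for s in (z0, y0, x0)]
    dst_hi = [min(n, s + w) for n, s, w in zip(tensor.source_shape, (z0, y0, x0), tensor.window_zyx)]
    src_hi = [lo + (hi - dlo) for lo, hi, dlo in zip(src_lo, dst_hi, dst_lo)]
    out[dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]] = values[
        src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
    ]
    return out
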