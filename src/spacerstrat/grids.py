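"""Voxel-grid containers shared by the whole pipeline.

Axis convention (used everywhere in this package): arrays are indexed
``(z, y, x)`` where ``z`` is cranio-caudal (index increases towards the
head), ``y`` is anterior->posterior (index increases posteriorly) and
``x`` is right->left.  ``spacing_mm`` and ``origin_mm`` follow the same
``(z, y, x)`` order.  Index ranges are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical structure names, in the fixed network-channel order.
STRUCTURES = ("ptv68", "ptv60", "ptv53", "rectum", "bladder")


class GridError(ValueError):
    """Raised for invalid or mutually inconsistent voxel grids."""


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GridError(f"spacing_mm must be 3 strictly positive reals, got {spacing_mm!r}")
    return spacing


@dataclass
class DoseGrid:
    """A scalar 3D dose field in Gy on a regular voxel grid."""

    dose_gy: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=np.float64)
        if self.dose_gy.ndim != 3:
            raise GridError(f"dose must be a 3D array, got shape {self.dose_gy.shape}")
        if not np.all(np.isfinite(self.dose_gy)):
            raise GridError("dose contains non-finite values")
        if np.any(self.dose_gy < 0):
            raise GridError("dose contains negative values")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose_gy.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class StructureSet:
    """Named boolean masks sharing one voxel grid.

    ``masks`` maps structure names to boolean ``(z, y, x)`` arrays.  A
    phantom carries six boost variants ``ptv68_a`` .. ``ptv68_f``;
    :meth:`select_boost` collapses one of them onto the canonical
    ``ptv68`` key expected by the network input.
    """

    masks: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if not self.masks:
            raise GridError("StructureSet requires at least one mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise GridError(f"all masks must share one grid shape, got {shapes}")
        for name, mask in self.masks.items():
            if mask.dtype != bool:
                self.masks[name] = mask.astype(bool)
            if not self.masks[name].any():
                raise GridError(f"mask '{name}' is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_cc

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def boost_names(self) -> list[str]:
        return sorted(n for n in self.masks if n.startswith("ptv68_"))

    def select_boost(self, boost_index: int) -> "StructureSet":
        """Return a canonical five-structure set for one PTV68 variant."""
        boosts = self.boost_names()
        if not boosts:
            raise GridError("structure set has no ptv68 boost variants")
        if not 0 <= boost_index < len(boosts):
            raise GridError(f"boost_index {boost_index} out of range 0..{len(boosts) - 1}")
        masks = {"ptv68": self.masks[boosts[boost_index]]}
        for name in ("ptv60", "ptv53", "rectum", "bladder"):
            masks[name] = self.masks[name]
        return StructureSet(masks, self.spacing_mm, self.origin_mm)
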