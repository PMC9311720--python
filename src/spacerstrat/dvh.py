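"""Cumulative dose-volume histograms and scalar DVH metrics.

A cumulative DVH reports, for each dose level d, the percentage v(d) of a
structure's volume receiving at least d Gy.  Curves here are tabulated on
fixed-width dose bins (0.1 Gy by default), start at v(0) = 100 and end at 0
one bin past the maximum dose.  Scalar queries (VdGy, Dv%, Dmean, Dmax)
interpolate linearly between bins, or use direct voxel statistics when the
raw dose grid is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, GridError

DEFAULT_BIN_WIDTH_GY = 0.1


class DVHError(ValueError):
    pass


@dataclass
class DVHCurve:
    """Cumulative DVH: ``cum_volume_pct[i]`` = % volume receiving >= ``dose_gy[i]``."""

    dose_gy: np.ndarray
    cum_volume_pct: np.ndarray
    structure: str = ""
    voxel_count: int = 0
    source: str = "planned"

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=np.float64)
        self.cum_volume_pct = np.asarray(self.cum_volume_pct, dtype=np.float64)
        if self.dose_gy.shape != self.cum_volume_pct.shape or self.dose_gy.ndim != 1:
            raise DVHError("dose and volume axes must be 1D arrays of equal length")
        if self.dose_gy.size < 2:
            raise DVHError("a DVH needs at least two points")
        if np.any(np.diff(self.dose_gy) <= 0):
            raise DVHError("dose axis must be strictly increasing")
        if np.any(np.diff(self.cum_volume_pct) > 1e-9):
            raise DVHError("cumulative volume must be non-increasing")

    @property
    def max_dose_gy(self) -> float:
        return float(self.dose_gy[-1])

    def v_at(self, dose_gy: float) -> float:
        """Volume (%) receiving at least ``dose_gy`` (linear interpolation)."""
        d = float(np.clip(dose_gy, self.dose_gy[0], self.dose_gy[-1]))
        return float(np.interp(d, self.dose_gy, self.cum_volume_pct))

    def d_at(self, volume_pct: float) -> float:
        """Dose (Gy) received by the hottest ``volume_pct`` % of the structure."""
        v = float(np.clip(volume_pct, self.cum_volume_pct[-1], self.cum_volume_pct[0]))
        # cum_volume_pct is non-increasing; flip for np.interp.
        return float(np.interp(v, self.cum_volume_pct[::-1], self.dose_gy[::-1]))

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """Fractional volumes per bin and bin-centre doses (for gEUD)."""
        frac = -np.diff(self.cum_volume_pct) / 100.0
        centres = 0.5 * (self.dose_gy[:-1] + self.dose_gy[1:])
        total = frac.sum()
        if total <= 0:
            raise DVHError("degenerate DVH: no volume in any bin")
        return frac / total, centres

    def mean_dose_gy(self) -> float:
        frac, centres = self.differential()
        return float(np.sum(frac * centres))


def compute_dvh(
    dose: DoseGrid,
    mask: np.ndarray,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    structure: str = "",
    source: str = "planned",
) -> DVHCurve:
    """Cumulative DVH by direct voxel counting."""
    if bin_width_gy <= 0:
        raise DVHError("bin_width_gy must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise GridError(f"mask shape {mask.shape} does not match dose shape {dose.shape}")
    if not mask.any():
        raise DVHError("cannot compute a DVH on an empty mask")
    values = dose.dose_gy[mask]
    n_bins = int(np.ceil(values.max() / bin_width_gy)) + 2
    edges = np.arange(n_bins + 1) * bin_width_gy
    counts, _ = np.histogram(values, bins=edges)
    # cumulative count of voxels with dose >= left edge of each bin
    cum = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    vol_pct = 100.0 * cum / values.size
    return DVHCurve(edges, vol_pct, structure=structure, voxel_count=int(values.size), source=source)


_QUERY_RE = re.compile(r"^(?:V(?P<dose>\d+(?:\.\d+)?)Gy|D(?P<vol>\d+(?:\.\d+)?)%)$", re.IGNORECASE)


def dvh_metric(curve_or_dose, query: str, mask: np.ndarray | None = None) -> float:
    """Evaluate a scalar DVH query.

    ``query`` is one of ``"VdGy"`` (volume % at dose d), ``"Dv%"`` (dose at
    hottest v %), ``"Dmax"`` or ``"Dmean"``.  Accepts either a
    :class:`DVHCurve` or a ``(DoseGrid, mask)`` pair; Dmax/Dmean use direct
    voxel statistics when voxels are available.
    """
    if isinstance(curve_or_dose, DoseGrid):
        if mask is None:
            raise DVHError("a mask is required when querying a DoseGrid")
        m = np.asarray(mask, dtype=bool)
        if not m.any():
            raise DVHError("empty mask")
        values = curve_or_dose.dose_gy[m]
        q = query.strip().lower()
        if q == "dmax":
            return float(values.max())
        if q == "dmean":
            return float(values.mean())
        if q == "dmin":
            return float(values.min())
        curve = compute_dvh(curve_or_dose, m)
    else:
        curve = curve_or_dose
        q = query.strip().lower()
        if q == "dmax":
            # highest dose with non-zero volume
            nz = np.nonzero(curve.cum_volume_pct > 0)[0]
            return float(curve.dose_gy[nz[-1] + 1]) if nz.size else 0.0
        if q == "dmean":
            return curve.mean_dose_gy()

    m = _QUERY_RE.match(query.strip())
    if not m:
        raise DVHError(f"unrecognised DVH query {query!r}")
    if m.group("dose") is not None:
        return curve.v_at(float(m.group("dose")))
    return curve.d_at(float(m.group("vol")))


def write_dvh(curve: DVHCurve, path) -> None:
    """Two-column tab-separated export (dose Gy, cumulative volume %)."""
    header = (
        f"# structure={curve.structure or 'unknown'} source={curve.source} "
        f"voxels={curve.voxel_count}\n# dose_gy\tvolume_pct\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for d, v in zip(curve.dose_gy, curve.cum_volume_pct):
            fh.write(f"{d:.4f}\t{v:.6f}\n")


def read_dvh(path) -> DVHCurve:
    structure, source, voxels = "", "planned", 0
    doses, vols = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("structure="):
                        structure = token.split("=", 1)[1]
                    elif token.startswith("source="):
                        source = token.split("=", 1)[1]
                    elif token.startswith("voxels="):
                        voxels = int(token.split("=", 1)[1])
                continue
            if line:
                d, v = line.split("\t")
                doses.append(float(d))
                vols.append(float(v))
    return DVHCurve(np.array(doses), np.array(vols), structure=structure, voxel_count=voxels, source=source)
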