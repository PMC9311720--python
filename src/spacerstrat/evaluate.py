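"""Prediction-quality metrics: DVH error profiles, isodose Dice, Bland-Altman."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dvh import DVHCurve, dvh_metric
from .grids import DoseGrid, GridError

log = logging.getLogger(__name__)

#: Isodose levels (Gy) evaluated by default: the plan's reported isodose set.
DEFAULT_DSC_LEVELS_GY = (24.6, 32.4, 40.8, 48.6, 60.0, 68.0)


class EvaluateError(ValueError):
    pass


def isodose_dsc(pred: DoseGrid, truth: DoseGrid, level_gy: float) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) of the supra-threshold voxel sets."""
    if level_gy <= 0:
        raise EvaluateError("isodose level must be positive")
    if not pred.same_grid(truth):
        raise GridError("predicted and true dose are on different grids")
    a = pred.dose_gy >= level_gy
    b = truth.dose_gy >= level_gy
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        log.info("isodose %.1f Gy empty in both volumes; DSC = 1 by convention", level_gy)
        return 1.0
    return 2.0 * int(np.sum(a & b)) / denom


def isodose_touches_boundary(dose: DoseGrid, level_gy: float) -> bool:
    """True if the supra-threshold region reaches any face of the grid."""
    m = dose.dose_gy >= level_gy
    return bool(
        m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any() or m[:, :, 0].any() or m[:, :, -1].any()
    )


def usable_dsc_levels(truth: DoseGrid, levels_gy=DEFAULT_DSC_LEVELS_GY) -> list[float]:
    """Levels whose true isodose is fully encompassed by the grid.

    Levels that touch the crop boundary are excluded (and logged): their
    Dice values would be truncated artefacts rather than prediction quality.
    """
    usable = []
    for level in levels_gy:
        if isodose_touches_boundary(truth, level):
            log.info("excluding %.1f Gy isodose: touches the volume boundary", level)
        else:
            usable.append(float(level))
    return usable


@dataclass
class ErrorSummary:
    mean: float
    median: float
    sd: float
    iqr: float
    whisker_low: float
    whisker_high: float
    n: int


def _summary(errors: np.ndarray) -> ErrorSummary:
    q1, med, q3 = np.percentile(errors, [25, 50, 75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    within = errors[(errors >= low_fence) & (errors <= high_fence)]
    return ErrorSummary(
        mean=float(errors.mean()),
        median=float(med),
        sd=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        iqr=float(iqr),
        whisker_low=float(within.min()),
        whisker_high=float(within.max()),
        n=int(errors.size),
    )


def dvh_error_profile(pairs, parameters) -> dict[str, ErrorSummary]:
    """Per-parameter summary of prediction errors over a cohort of DVH pairs.

    ``pairs`` is a sequence of ``(predicted DVHCurve, planned DVHCurve)``;
    errors are predicted minus planned, so a positive mean is an
    over-prediction.  V-parameters are compared in percentage points.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise EvaluateError("need at least two DVH pairs for an error profile")
    out = {}
    for param in parameters:
        errs = np.array([dvh_metric(p, param) - dvh_metric(t, param) for p, t in pairs])
        out[param] = _summary(errs)
    return out


@dataclass
class BlandAltmanResult:
    mean_bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray

    def __post_init__(self) -> None:
        if not self.loa_low <= self.mean_bias <= self.loa_high:
            raise EvaluateError("limits of agreement must bracket the mean bias")


def bland_altman(pred, truth) -> BlandAltmanResult:
    """Paired-difference agreement: bias and mean +- 1.96 * SD limits.

    Sample SD (n - 1 denominator) is used for the limits of agreement.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise EvaluateError("paired sequences differ in length")
    if pred.size < 2:
        raise EvaluateError("Bland-Altman needs at least two pairs")
    diff = pred - truth
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, diff)
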