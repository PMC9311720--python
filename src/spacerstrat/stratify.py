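"""Rectal-spacer risk stratification and its accuracy accounting.

Four stratification methods are supported: exceeding optimal rectal DVH
constraints, exceeding mandatory constraints, and thresholding either the
late-rectal-bleeding or the fecal-incontinence risk.  The positive class is
always "exceeds tolerance / high risk".  A plan sitting exactly on a DVH
constraint passes (strict >), whereas a risk exactly at the threshold is
classified high (>=), matching the clinical phrasing "offer insertion to
patients with risk >= threshold".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .dvh import DVHCurve, dvh_metric


class StratifyError(ValueError):
    pass


@dataclass(frozen=True)
class ConstraintEntry:
    dose_gy: float
    max_volume_pct: float
    level: str  # "optimal" | "mandatory"

    def __post_init__(self) -> None:
        if self.dose_gy <= 0:
            raise StratifyError("constraint dose must be positive")
        if not 0 <= self.max_volume_pct <= 100:
            raise StratifyError("constraint volume must be in [0, 100] %")
        if self.level not in ("optimal", "mandatory"):
            raise StratifyError(f"unknown constraint level {self.level!r}")

    @property
    def metric(self) -> str:
        d = self.dose_gy
        return f"V{d:g}Gy"


@dataclass
class ConstraintTable:
    entries: list[ConstraintEntry]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise StratifyError("constraint table has no entries")
        # nested leniency: mandatory threshold >= optimal threshold at the same dose
        opt = {e.dose_gy: e.max_volume_pct for e in self.entries if e.level == "optimal"}
        for e in self.entries:
            if e.level == "mandatory" and e.dose_gy in opt and e.max_volume_pct < opt[e.dose_gy]:
                raise StratifyError(
                    f"mandatory tolerance at {e.dose_gy} Gy is stricter than the optimal one"
                )

    def at_level(self, level: str) -> list[ConstraintEntry]:
        entries = [e for e in self.entries if e.level == level]
        if not entries:
            raise StratifyError(f"constraint table has no entries at level {level!r}")
        return entries

    @classmethod
    def from_yaml(cls, path) -> "ConstraintTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        entries = [
            ConstraintEntry(float(e["dose_gy"]), float(e["max_volume_pct"]), str(e["level"]))
            for e in data["entries"]
        ]
        return cls(entries, source=str(data.get("source", "")))

    def to_yaml(self, path) -> None:
        data = {
            "source": self.source,
            "entries": [
                {"dose_gy": e.dose_gy, "max_volume_pct": e.max_volume_pct, "level": e.level}
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_constraint_table() -> ConstraintTable:
    """Nested rectal tolerance table for the 20-fraction three-level plans.

    Derived from the Onjukka-style dose-escalation tolerances (user
    overridable); the top-dose tolerance is 0.2 % rather than 0 % for
    practical planning reasons.
    """
    rows = [
        # dose_gy, optimal %, mandatory %
        (24.6, 55.0, 65.0),
        (32.4, 45.0, 55.0),
        (40.8, 30.0, 40.0),
        (48.6, 15.0, 25.0),
        (57.0, 2.6, 5.2),
        (60.0, 0.9, 1.9),
        (68.0, 0.2, 0.2),
    ]
    entries = []
    for dose, opt, mand in rows:
        entries.append(ConstraintEntry(dose, opt, "optimal"))
        entries.append(ConstraintEntry(dose, mand, "mandatory"))
    return ConstraintTable(entries, source="Onjukka-derived defaults (synthetic study table)")


@dataclass
class StratificationOutcome:
    method: str  # optimal_dvh | mandatory_dvh | lrb_risk | lfi_risk
    label: str  # "high" | "low"
    margin: float  # signed distance to the binding threshold
    binding: str  # id of the binding constraint / threshold

    @property
    def is_high(self) -> bool:
        return self.label == "high"


def check_constraints(rect_dvh: DVHCurve, table: ConstraintTable, level: str) -> StratificationOutcome:
    """Label a rectal DVH against one constraint level.

    High iff any VdGy strictly exceeds its tolerance; exact equality counts
    as within tolerance.  The margin is the worst (largest) signed excess in
    percentage points.
    """
    entries = table.at_level(level)
    margins = [(dvh_metric(rect_dvh, e.metric) - e.max_volume_pct, e) for e in entries]
    margin, entry = max(margins, key=lambda t: t[0])
    label = "high" if margin > 0 else "low"
    return StratificationOutcome(
        method=f"{level}_dvh", label=label, margin=float(margin), binding=f"{entry.metric}<={entry.max_volume_pct:g}%"
    )


def stratify_by_risk(risk: float, threshold: float, endpoint: str = "lrb") -> StratificationOutcome:
    """High iff risk >= threshold (equality stratifies high)."""
    if not 0 <= risk <= 1 or not 0 <= threshold <= 1:
        raise StratifyError("risk and threshold must be probabilities in [0, 1]")
    margin = risk - threshold
    label = "high" if margin >= 0 else "low"
    return StratificationOutcome(
        method=f"{endpoint.lower()}_risk", label=label, margin=float(margin), binding=f"risk>={threshold:g}"
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Positive class = exceeds tolerance / high risk."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise StratifyError("confusion counts must be non-negative")
        if self.total == 0:
            raise StratifyError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, pred_high, truth_high) -> "ConfusionCounts":
        pred = np.asarray(pred_high, dtype=bool)
        truth = np.asarray(truth_high, dtype=bool)
        if pred.shape != truth.shape:
            raise StratifyError("prediction and truth label lists differ in length")
        return cls(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            tn=int(np.sum(~pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity and accuracy with undefined-denominator flags."""
    out: dict = {"counts": c}
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    out["sensitivity"] = c.tp / pos if pos else None
    out["specificity"] = c.tn / neg if neg else None
    out["accuracy"] = (c.tp + c.tn) / c.total
    out["undefined"] = [k for k in ("sensitivity", "specificity") if out[k] is None]
    return out


def threshold_sweep(pred_risks, truth_risks, thresholds) -> np.ndarray:
    """Fraction of patients with agreeing high/low labels at each threshold."""
    pred = np.asarray(pred_risks, dtype=np.float64)
    truth = np.asarray(truth_risks, dtype=np.float64)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if pred.size == 0 or truth.size == 0 or thresholds.size == 0:
        raise StratifyError("empty input to threshold sweep")
    if pred.shape != truth.shape:
        raise StratifyError("paired risk sequences differ in length")
    agree = (pred[None, :] >= thresholds[:, None]) == (truth[None, :] >= thresholds[:, None])
    return agree.mean(axis=1)
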