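"""Stage orchestration: simulate -> preprocess -> train -> predict -> evaluate -> stratify.

Every stage reads its inputs from, and writes its artifacts under, one run
directory, so stages can be re-run individually; a manifest records the
configuration, seeds and artifact hashes.  Identical configuration and seed
reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .dvh import compute_dvh, dvh_metric
from .evaluate import DEFAULT_DSC_LEVELS_GY, bland_altman, isodose_dsc, usable_dsc_levels
from .grids import DoseGrid
from .nn.network import HDUNet, NetworkConfig
from .nn.training import TrainingConfig, train
from .phantom import BOOST_LETTERS, FalloffConfig, PhantomSpec, generate_phantom, label_plan, simulate_plan_dose
from .preprocess import (
    DESK_SCALE_WINDOW_XYZ,
    ModelInputTensor,
    NormalizationConstant,
    crop_to_input,
    normalize,
)
from .evaluate import dvh_error_profile
from .radiobiology import FractionationScheme, risk
from .stratify import (
    ConfusionCounts,
    ConstraintTable,
    check_constraints,
    confusion_metrics,
    default_constraint_table,
    stratify_by_risk,
    threshold_sweep,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "predict", "evaluate", "stratify")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run (desk-scale defaults)."""

    seed: int = 0
    n_train: int = 20
    n_test: int = 14
    window_xyz: tuple[int, int, int] = DESK_SCALE_WINDOW_XYZ
    levels: int = 3
    growth: int = 4
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 6
    n_fractions: int = 20
    dsc_levels_gy: tuple[float, ...] = DEFAULT_DSC_LEVELS_GY
    constraints_yaml: str | None = None
    lrb_threshold: float = 0.064
    lfi_threshold: float = 0.038

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(levels=self.levels, growth=self.growth)

    def training_config(self, seed: int) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=seed,
        )

    def constraint_table(self) -> ConstraintTable:
        if self.constraints_yaml:
            return ConstraintTable.from_yaml(self.constraints_yaml)
        return default_constraint_table()

    def fractionation(self) -> FractionationScheme:
        return FractionationScheme(n_fractions=self.n_fractions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = sio.read_sidecar(path) or {}
        for key in ("window_xyz", "dsc_levels_gy"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _sub_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(stage_dir: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    files = sorted(p for p in stage_dir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": sio._plain(cfg),
        "artifacts": {str(p.relative_to(stage_dir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(sio._plain(extra))
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    """Generate training and test phantoms with labelled analytic plans."""
    sim_dir = out / "phantoms"
    sim_dir.mkdir(parents=True, exist_ok=True)
    table = cfg.constraint_table()
    fx = cfg.fractionation()
    phantom_seeds = _sub_seeds(cfg.seed, cfg.n_train + cfg.n_test)
    plan_seed_rng = np.random.default_rng(cfg.seed + 1)
    index = []
    for i, pseed in enumerate(phantom_seeds):
        is_test = i >= cfg.n_train
        pid = f"{'test' if is_test else 'train'}_{i:03d}"
        spec = PhantomSpec.desk(pseed) if cfg.window_xyz == DESK_SCALE_WINDOW_XYZ else PhantomSpec.sample(pseed)
        anatomy = generate_phantom(spec)
        pdir = sim_dir / pid
        sio.write_structures(anatomy, pdir / "structures")
        boosts = range(6) if not is_test else [int(plan_seed_rng.integers(0, 6))]
        for b in boosts:
            falloff = FalloffConfig.sample(int(plan_seed_rng.integers(0, 2**31 - 1)))
            dose = simulate_plan_dose(anatomy, b, falloff)
            label = label_plan(anatomy.select_boost(b), dose, table, fx)
            sio.write_dose(dose, pdir / f"plan_{BOOST_LETTERS[b]}_dose.nii")
            sio.write_sidecar(
                pdir / f"plan_{BOOST_LETTERS[b]}.yaml",
                patient=pid,
                boost=BOOST_LETTERS[b],
                spec=spec,
                falloff=falloff,
                label=label,
            )
            index.append({"patient": pid, "boost": BOOST_LETTERS[b], "split": "test" if is_test else "train"})
    pd.DataFrame(index).to_csv(sim_dir / "plans.csv", index=False)
    _write_manifest(sim_dir, cfg)


def _load_plan(sim_dir: Path, patient: str, boost: str):
    pdir = sim_dir / patient
    anatomy = sio.read_structures(pdir / "structures")
    dose = sio.read_dose(pdir / f"plan_{boost}_dose.nii")
    meta = sio.read_sidecar(pdir / f"plan_{boost}.yaml")
    return anatomy, dose, meta


def _plan_index(out: Path) -> pd.DataFrame:
    path = out / "phantoms" / "plans.csv"
    if not path.exists():
        raise PipelineError("no simulated phantoms found; run the 'simulate' stage first")
    return pd.read_csv(path)


def stage_preprocess(cfg: RunConfig, out: Path) -> None:
    """Crop every plan to the network window and store normalized tensors."""
    sim_dir = out / "phantoms"
    pre_dir = out / "preprocessed"
    pre_dir.mkdir(parents=True, exist_ok=True)
    plans = _plan_index(out)
    crops = {}
    for _, row in plans.iterrows():
        anatomy, dose, _ = _load_plan(sim_dir, row.patient, row.boost)
        tensor, cropped = crop_to_input(anatomy.select_boost(BOOST_LETTERS.index(row.boost)), dose, cfg.window_xyz)
        crops[(row.patient, row.boost)] = (tensor, cropped)
    train_max = max(
        float(cropped.dose_gy.max())
        for (pid, _), (_, cropped) in crops.items()
        if pid.startswith("train")
    )
    norm = NormalizationConstant(train_max, cohort_id="training")
    for (pid, boost), (tensor, cropped) in crops.items():
        np.savez(
            pre_dir / f"{pid}_{boost}.npz",
            channels=tensor.channels,
            dose_norm=normalize(cropped, norm).astype(np.float32),
            crop_offset=np.array(tensor.crop_offset),
            spacing_mm=np.array(tensor.spacing_mm),
            source_shape=np.array(tensor.source_shape),
        )
    (pre_dir / "normalization.json").write_text(
        json.dumps({"max_dose_gy": norm.max_dose_gy, "cohort_id": norm.cohort_id})
    )
    _write_manifest(pre_dir, cfg)


def _load_tensor(path: Path) -> tuple[ModelInputTensor, np.ndarray]:
    with np.load(path) as d:
        tensor = ModelInputTensor(
            channels=d["channels"],
            crop_offset=tuple(int(v) for v in d["crop_offset"]),
            spacing_mm=tuple(float(v) for v in d["spacing_mm"]),
            source_shape=tuple(int(v) for v in d["source_shape"]),
        )
        return tensor, d["dose_norm"].astype(np.float32)


def _load_split(cfg: RunConfig, out: Path, split: str):
    pre_dir = out / "preprocessed"
    if not (pre_dir / "normalization.json").exists():
        raise PipelineError("no preprocessed tensors found; run the 'preprocess' stage first")
    norm_data = json.loads((pre_dir / "normalization.json").read_text())
    norm = NormalizationConstant(**norm_data)
    plans = _plan_index(out)
    items = []
    for _, row in plans[plans.split == split].iterrows():
        tensor, dose_norm = _load_tensor(pre_dir / f"{row.patient}_{row.boost}.npz")
        items.append((f"{row.patient}_{row.boost}", tensor, dose_norm))
    return items, norm


def stage_train(cfg: RunConfig, out: Path) -> None:
    items, norm = _load_split(cfg, out, "train")
    seeds = _sub_seeds(cfg.seed + 2, 2)
    net = HDUNet(cfg.network_config(), seed=seeds[0])
    model = train(
        net,
        [(t, d) for _, t, d in items],
        cfg.training_config(seeds[1]),
        norm,
        plan_ids=[pid for pid, _, _ in items],
    )
    model_dir = out / "model"
    model_dir.mkdir(parents=True, exist_ok=True)
    sio.save_checkpoint(model, cfg.network_config(), model_dir / "model")
    _write_manifest(model_dir, cfg, extra={"final_loss": model.manifest["final_loss"]})


def stage_predict(cfg: RunConfig, out: Path) -> None:
    model_path = out / "model" / "model"
    if not model_path.with_suffix(".npz").exists():
        raise PipelineError("no trained model found; run the 'train' stage first")
    model, _ = sio.load_checkpoint(model_path)
    items, _ = _load_split(cfg, out, "test")
    pred_dir = out / "predictions"
    pred_dir.mkdir(parents=True, exist_ok=True)
    for pid, tensor, _ in items:
        sio.write_dose(model.predict_dose(tensor), pred_dir / f"{pid}_pred.nii")
    _write_manifest(pred_dir, cfg)


def _test_pairs(cfg: RunConfig, out: Path):
    """(plan id, tensor, predicted DoseGrid, true DoseGrid in crop frame)."""
    pred_dir = out / "predictions"
    if not pred_dir.exists():
        raise PipelineError("no predictions found; run the 'predict' stage first")
    items, norm = _load_split(cfg, out, "test")
    out_pairs = []
    for pid, tensor, dose_norm in items:
        pred = sio.read_dose(pred_dir / f"{pid}_pred.nii")
        truth = DoseGrid(dose_norm.astype(np.float64) * norm.max_dose_gy, pred.spacing_mm, pred.origin_mm)
        out_pairs.append((pid, tensor, pred, truth))
    return out_pairs


def _baseline_dose(cfg: RunConfig, out: Path) -> np.ndarray:
    """Cohort-mean baseline: the voxelwise mean of all training doses (Gy)."""
    items, norm = _load_split(cfg, out, "train")
    return np.mean([d for _, _, d in items], axis=0).astype(np.float64) * norm.max_dose_gy


def stage_evaluate(cfg: RunConfig, out: Path) -> dict:
    fx = cfg.fractionation()
    pairs = _test_pairs(cfg, out)
    baseline = _baseline_dose(cfg, out)
    eval_dir = out / "evaluation"
    eval_dir.mkdir(parents=True, exist_ok=True)

    rows, dsc_rows = [], []
    pred_lrb, truth_lrb, pred_lfi, truth_lfi = [], [], [], []
    for pid, tensor, pred, truth in pairs:
        rectum = tensor.mask("rectum")
        row = {
            "plan": pid,
            "dmean_pred": dvh_metric(pred, "Dmean", rectum),
            "dmean_truth": dvh_metric(truth, "Dmean", rectum),
            "dmean_baseline": float(np.mean(baseline[rectum])),
            "dmax_pred": dvh_metric(pred, "Dmax", rectum),
            "dmax_truth": dvh_metric(truth, "Dmax", rectum),
        }
        pc = compute_dvh(pred, rectum, structure="rectum", source="predicted")
        tc = compute_dvh(truth, rectum, structure="rectum", source="planned")
        pred_lrb.append(risk(pc, "LRB", fx))
        truth_lrb.append(risk(tc, "LRB", fx))
        pred_lfi.append(risk(pc, "LFI", fx))
        truth_lfi.append(risk(tc, "LFI", fx))
        rows.append(row)
        for level in usable_dsc_levels(truth, cfg.dsc_levels_gy):
            dsc_rows.append({"plan": pid, "level_gy": level, "dsc": isodose_dsc(pred, truth, level)})

    df = pd.DataFrame(rows)
    df["dmean_err"] = df.dmean_pred - df.dmean_truth
    df["dmean_baseline_err"] = df.dmean_baseline - df.dmean_truth
    df.to_csv(eval_dir / "dose_metrics.csv", index=False)
    pd.DataFrame(dsc_rows).to_csv(eval_dir / "dsc.csv", index=False)

    # per-parameter rectal DVH error distribution (predicted minus planned)
    dvh_pairs = [
        (compute_dvh(pred, tensor.mask("rectum")), compute_dvh(truth, tensor.mask("rectum")))
        for _, tensor, pred, truth in pairs
    ]
    params = [e.metric for e in cfg.constraint_table().at_level("optimal")]
    profile = dvh_error_profile(dvh_pairs, params)
    pd.DataFrame(
        [{"parameter": k, **vars(v)} for k, v in profile.items()]
    ).to_csv(eval_dir / "dvh_error_profile.csv", index=False)

    ba_lrb = bland_altman(np.array(pred_lrb) * 100, np.array(truth_lrb) * 100)
    ba_lfi = bland_altman(np.array(pred_lfi) * 100, np.array(truth_lfi) * 100)
    mae_model = float(np.abs(df.dmean_err).mean())
    mae_baseline = float(np.abs(df.dmean_baseline_err).mean())
    summary = {
        "n_test": len(pairs),
        "rectal_dmean_mae_gy": mae_model,
        "rectal_dmean_baseline_mae_gy": mae_baseline,
        "mae_improvement_fraction": 1.0 - mae_model / mae_baseline if mae_baseline > 0 else 0.0,
        "mean_dsc": float(np.mean([r["dsc"] for r in dsc_rows])) if dsc_rows else None,
        "bland_altman_lrb_pct": {"bias": ba_lrb.mean_bias, "loa_low": ba_lrb.loa_low, "loa_high": ba_lrb.loa_high},
        "bland_altman_lfi_pct": {"bias": ba_lfi.mean_bias, "loa_low": ba_lfi.loa_low, "loa_high": ba_lfi.loa_high},
        "pred_lrb": pred_lrb,
        "truth_lrb": truth_lrb,
        "pred_lfi": pred_lfi,
        "truth_lfi": truth_lfi,
    }
    (eval_dir / "summary.json").write_text(json.dumps(sio._plain(summary), indent=2, sort_keys=True))
    _write_manifest(eval_dir, cfg)
    return summary


def stage_stratify(cfg: RunConfig, out: Path) -> dict:
    """All four stratification methods: optimal/mandatory DVH constraints and
    the two risk thresholds, plus the threshold-sweep agreement curve."""
    table = cfg.constraint_table()
    fx = cfg.fractionation()
    pairs = _test_pairs(cfg, out)
    strat_dir = out / "stratification"
    strat_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    risks = {"lrb": ([], []), "lfi": ([], [])}
    for pid, tensor, pred, truth in pairs:
        rectum = tensor.mask("rectum")
        pc = compute_dvh(pred, rectum, structure="rectum", source="predicted")
        tcv = compute_dvh(truth, rectum, structure="rectum", source="planned")
        for level in ("optimal", "mandatory"):
            po = check_constraints(pc, table, level)
            to = check_constraints(tcv, table, level)
            rows.append(
                {
                    "plan": pid,
                    "method": po.method,
                    "pred_label": po.label,
                    "truth_label": to.label,
                    "pred_margin": round(po.margin, 6),
                    "truth_margin": round(to.margin, 6),
                    "binding": po.binding,
                }
            )
        for endpoint, threshold in (("lrb", cfg.lrb_threshold), ("lfi", cfg.lfi_threshold)):
            pr = risk(pc, endpoint.upper(), fx)
            tr = risk(tcv, endpoint.upper(), fx)
            risks[endpoint][0].append(pr)
            risks[endpoint][1].append(tr)
            po = stratify_by_risk(pr, threshold, endpoint)
            to = stratify_by_risk(tr, threshold, endpoint)
            rows.append(
                {
                    "plan": pid,
                    "method": po.method,
                    "pred_label": po.label,
                    "truth_label": to.label,
                    "pred_margin": round(po.margin, 6),
                    "truth_margin": round(to.margin, 6),
                    "binding": po.binding,
                }
            )
    df = pd.DataFrame(rows).sort_values(["method", "plan"]).reset_index(drop=True)
    df.to_csv(strat_dir / "report.csv", index=False)

    # agreement between predicted- and planned-risk labels vs threshold
    thresholds = np.round(np.arange(0.01, 0.151, 0.005), 4)
    sweep = pd.DataFrame({"threshold": thresholds})
    for endpoint, (pred_r, truth_r) in risks.items():
        sweep[f"{endpoint}_agreement"] = threshold_sweep(pred_r, truth_r, thresholds)
    sweep.to_csv(strat_dir / "threshold_sweep.csv", index=False)

    summary = {}
    for method in sorted(df.method.unique()):
        sub = df[df.method == method]
        counts = ConfusionCounts.from_labels(sub.pred_label == "high", sub.truth_label == "high")
        metrics = confusion_metrics(counts)
        summary[method.replace("_dvh", "")] = {
            "tp": counts.tp,
            "fp": counts.fp,
            "tn": counts.tn,
            "fn": counts.fn,
            "accuracy": metrics["accuracy"],
            "sensitivity": metrics["sensitivity"],
            "specificity": metrics["specificity"],
        }
    (strat_dir / "summary.json").write_text(json.dumps(sio._plain(summary), indent=2, sort_keys=True))
    _write_manifest(strat_dir, cfg)
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "predict": stage_predict,
    "evaluate": stage_evaluate,
    "stratify": stage_stratify,
}


def run_pipeline(cfg: RunConfig, out_dir, stages=STAGES) -> dict:
    """Run the requested stages in canonical order; returns stage summaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; valid stages are {list(STAGES)}")
    results = {}
    for stage in STAGES:
        if stage in stages:
            log.info("running stage '%s'", stage)
            results[stage] = _STAGE_FUNCS[stage](cfg, out)
    return results


def replicate_small(seed: int, out_dir, cfg: RunConfig | None = None) -> dict:
    """The desk-scale end-to-end experiment: 20 training phantoms x 6 boosts,
    14 held-out phantoms, 32 x 32 x 16 crops; returns the combined summary."""
    cfg = replace(cfg, seed=seed) if cfg is not None else RunConfig(seed=seed)
    results = run_pipeline(cfg, out_dir, STAGES)
    return {"config": sio._plain(cfg), "evaluate": results["evaluate"], "stratify": results["stratify"]}
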