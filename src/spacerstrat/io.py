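"""File formats: NIfTI volumes, YAML sidecars, model checkpoints.

Volumes are written as NIfTI-1 with an affine mapping voxel indices
``(z, y, x)`` to physical mm; masks as uint8, dose as float32.  A model
checkpoint is an ``.npz`` of weight arrays plus a JSON manifest carrying
the architecture, training configuration and normalization constant.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import DoseGrid, StructureSet
from .nn.network import HDUNet, NetworkConfig
from .nn.training import TrainedModel, TrainingConfig
from .preprocess import NormalizationConstant


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = spacing_mm[i]
        aff[i, 3] = origin_mm[i]
    return aff


def write_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.dose_gy.astype(np.float32), _affine(dose.spacing_mm, dose.origin_mm))
    nib.save(img, str(path))


def read_dose(path) -> DoseGrid:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return DoseGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def write_structures(anatomy: StructureSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(anatomy.spacing_mm, anatomy.origin_mm)
    for name, mask in anatomy.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), str(directory / f"{name}.nii"))


def read_structures(directory) -> StructureSet:
    directory = Path(directory)
    paths = sorted(directory.glob("*.nii")) + sorted(directory.glob("*.nii.gz"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI structures under {directory}")
    masks, spacing, origin = {}, None, None
    for p in paths:
        img = nib.load(str(p))
        name = p.name.removesuffix(".gz").removesuffix(".nii")
        masks[name] = np.asarray(img.dataobj).astype(bool)
        spacing = tuple(float(img.affine[i, i]) for i in range(3))
        origin = tuple(float(img.affine[i, 3]) for i in range(3))
    return StructureSet(masks, spacing, origin)


def write_sidecar(path, **payload) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=False)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert dataclasses / numpy scalars for YAML/JSON."""
    if hasattr(obj, "__dataclass_fields__"):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_checkpoint(model: TrainedModel, net_cfg: NetworkConfig, path) -> None:
    path = Path(path)
    arrays = {f"p{i:03d}": a for i, a in enumerate(model.net.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {
        "network": _plain(net_cfg),
        "training": _plain(model.training_config),
        "normalization": _plain(model.norm_const),
        "manifest": _plain(model.manifest),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> tuple[TrainedModel, NetworkConfig]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    net_cfg = NetworkConfig(**manifest["network"])
    net = HDUNet(net_cfg, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_arrays([data[k] for k in sorted(data.files)])
    model = TrainedModel(
        net=net,
        training_config=TrainingConfig(**manifest["training"]),
        norm_const=NormalizationConstant(**manifest["normalization"]),
        manifest=manifest["manifest"],
    )
    return model, net_cfg
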