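"""Training loop, Adam optimiser, prediction and the LOOCV harness."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from ..grids import DoseGrid
from ..preprocess import ModelInputTensor, NormalizationConstant, denormalize
from .autograd import Tensor
from .network import HDUNet, NetworkConfig
from .ops import mse_loss

log = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise TrainingError("learning rate must be positive")
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")
        if self.batch_size < 1:
            raise TrainingError("batch size must be >= 1")

    @classmethod
    def desk_scale(cls, epochs: int = 50, seed: int = 0) -> "TrainingConfig":
        return cls(learning_rate=1e-3, epochs=epochs, batch_size=6, seed=seed)


class Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainedModel:
    """Network weights plus everything needed to predict dose in Gy."""

    net: HDUNet
    training_config: TrainingConfig
    norm_const: NormalizationConstant
    manifest: dict = field(default_factory=dict)

    def predict_dose(self, x: ModelInputTensor) -> DoseGrid:
        """Predict the dose for one input crop, rescaled to Gy and clamped at 0."""
        batch = x.channels[None].astype(np.float32)
        t0 = time.perf_counter()
        raw = self.net.predict(batch)[0, 0]
        log.info("dose prediction took %.3f s", time.perf_counter() - t0)
        dose = np.clip(denormalize(raw, self.norm_const), 0.0, None)
        z0, y0, x0 = x.crop_offset
        origin = tuple(i * s for i, s in zip((z0, y0, x0), x.spacing_mm))
        return DoseGrid(dose, x.spacing_mm, origin)


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    net: HDUNet,
    dataset: list[tuple[ModelInputTensor, np.ndarray]],
    tc: TrainingConfig,
    norm_const: NormalizationConstant,
    plan_ids: list[str] | None = None,
) -> TrainedModel:
    """Minimise voxelwise MSE between predicted and planned normalized dose.

    ``dataset`` pairs each input tensor with its normalized dose volume
    (``(z, y, x)`` float array on the unit scale).  Fully deterministic for
    a fixed ``tc.seed``: batch order is drawn from a dedicated generator.
    """
    if not dataset:
        raise TrainingError("training dataset is empty")
    shapes = {x.channels.shape for x, _ in dataset}
    if len(shapes) != 1:
        raise TrainingError(f"all input tensors must share one shape, got {shapes}")

    xs = np.stack([x.channels for x, _ in dataset]).astype(np.float32)
    ys = np.stack([y for _, y in dataset]).astype(np.float32)[:, None]

    rng = np.random.default_rng(tc.seed)
    opt = Adam(net.params, lr=tc.learning_rate)
    history = []
    for epoch in range(tc.epochs):
        epoch_loss, n_batches = 0.0, 0
        for batch_idx in _as_batches(len(dataset), tc.batch_size, rng):
            opt.zero_grad()
            loss = mse_loss(net.forward(Tensor(xs[batch_idx])), ys[batch_idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}; aborting"
                )
            loss.backward()
            opt.step()
            epoch_loss += value
            n_batches += 1
        history.append(epoch_loss / n_batches)
        if epoch == 0 or (epoch + 1) % 10 == 0:
            log.info("epoch %d/%d  mse %.3e", epoch + 1, tc.epochs, history[-1])

    manifest = {
        "plan_ids": list(plan_ids) if plan_ids is not None else list(range(len(dataset))),
        "seed": tc.seed,
        "epochs": tc.epochs,
        "loss_history": history,
        "final_loss": history[-1],
    }
    return TrainedModel(net=net, training_config=tc, norm_const=norm_const, manifest=manifest)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation, grouped by patient


def loocv_folds(plan_patients: list[str]) -> list[dict]:
    """Patient-grouped LOOCV split manifest.

    ``plan_patients[i]`` is the patient id owning plan ``i``.  Each fold
    holds out every plan of one patient; no plan of a held-out patient ever
    appears in its training set.
    """
    patients = sorted(set(plan_patients))
    if len(patients) < 2:
        raise TrainingError("LOOCV needs at least two patients")
    counts = {p: plan_patients.count(p) for p in patients}
    expected = max(counts.values())
    short = [p for p, c in counts.items() if c != expected]
    if short:
        raise TrainingError(f"patients with missing boost plans: {short}")
    folds = []
    for held in patients:
        train_idx = [i for i, p in enumerate(plan_patients) if p != held]
        test_idx = [i for i, p in enumerate(plan_patients) if p == held]
        folds.append({"held_out": held, "train": train_idx, "test": test_idx})
    return folds


def run_loocv(
    dataset: list[tuple[ModelInputTensor, np.ndarray]],
    plan_patients: list[str],
    net_cfg: NetworkConfig,
    tc: TrainingConfig,
    norm_const: NormalizationConstant,
) -> dict:
    """Train one model per fold and predict each held-out patient's plans."""
    if len(dataset) != len(plan_patients):
        raise TrainingError("dataset and patient list differ in length")
    folds = loocv_folds(plan_patients)
    predictions: dict[int, DoseGrid] = {}
    fold_manifests = []
    for f, fold in enumerate(folds):
        net = HDUNet(net_cfg, seed=tc.seed + f)
        model = train(
            net,
            [dataset[i] for i in fold["train"]],
            tc,
            norm_const,
            plan_ids=[str(i) for i in fold["train"]],
        )
        for i in fold["test"]:
            assert i not in fold["train"]
            predictions[i] = model.predict_dose(dataset[i][0])
        fold_manifests.append(
            {
                "held_out": fold["held_out"],
                "n_train": len(fold["train"]),
                "n_test": len(fold["test"]),
                "final_loss": model.manifest["final_loss"],
            }
        )
    return {"predictions": predictions, "folds": fold_manifests}
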