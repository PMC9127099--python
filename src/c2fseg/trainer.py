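"""Training on coarse label pairs, endpoint selection and fine-label export.

The network never sees a pixel-accurate target.  Each image carries an
ordered list of coarse targets — typically [MGRL, CDTL], extensible to any
number (multi-target single output) — and the loss is the unweighted sum of
one term per target:

    L_all = sum_t L(O, target_t)

with L the mean squared error for a single class and pixel-averaged cross
entropy for multiple classes.  For the binary case the two targets bracket
the object (MGRL over-covers, CDTL under-covers inside the MGRL), so the
MSE optimum sits near (C + P)/2 and the 0.7 prediction threshold carves out
the region both targets agree on — the fine label.

Training drifts: run long enough, predictions approach the rough labels
themselves.  The endpoint is therefore selected by tracking, each epoch, the
mIOU of thresholded predictions on a small validation subset with fine
labels; the subset is *embedded* in the training data (the artifact's goal
is labelling its own training set, so holding images out would be wasted
annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import evaluate_dataset
from .segmodel import SegModel, image_to_input, predict_mask

__all__ = [
    "TrainConfig",
    "TrainSample",
    "EpochRecord",
    "TrainingHistory",
    "clp_loss",
    "split_with_embedded_validation",
    "train",
    "select_endpoint",
    "generate_plfl",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    Defaults follow the reference protocol for field-scale binary labelling:
    40 epochs, batch 12, Adam at lr 0.005, prediction threshold 0.7.  Circle
    scenes converge in ~5 epochs; public leaf datasets used 50.
    """

    epochs: int = 40
    batch_size: int = 12
    learning_rate: float = 0.005
    loss_kind: str = "auto"  # mse | cross_entropy | auto (mse iff single class)
    prediction_threshold: float = 0.7
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.loss_kind not in ("auto", "mse", "cross_entropy"):
            raise ValueError("loss_kind must be auto, mse or cross_entropy")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainSample:
    """One training item: image, its coarse targets, and (optionally) the
    fine label used only if the sample lands in the validation subset."""

    image: np.ndarray
    targets: list[np.ndarray]
    fine_label: np.ndarray | None = None
    mgrl: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("a TrainSample needs at least one coarse target")
        for t in self.targets:
            if t.shape != self.image.shape[:2]:
                raise ValueError("all targets must share the image's spatial shape")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    val_miou: float
    mgrl_similarity: float  # mean IOU of thresholded predictions vs the MGRLs

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "train_loss": self.train_loss,
            "val_miou": self.val_miou,
            "mgrl_similarity": self.mgrl_similarity,
        }


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_state: dict | None = None
    last_state: dict | None = None

    @property
    def best_epoch(self) -> int:
        """Epoch with the highest validation mIOU; earliest on ties."""
        if not self.records:
            raise ValueError("empty history")
        mious = [r.val_miou for r in self.records]
        return int(np.argmax(mious))  # argmax returns the first maximum

    def to_dict(self) -> dict:
        return {"records": [r.to_dict() for r in self.records], "best_epoch": self.best_epoch}


def clp_loss(o: np.ndarray, targets: list[np.ndarray], kind: str) -> float:
    """Coarse-label-pair loss: unweighted sum of one term per target.

    ``o`` is a probability map — (H, W) (or (1, H, W)) for MSE, or
    (K+1, H, W) channel probabilities for cross entropy, where targets are
    integer label masks.
    """
    if not targets:
        raise ValueError("empty target list")
    o = np.asarray(o, dtype=np.float64)
    if kind == "mse":
        if o.ndim == 3:
            o = o[0]
        return float(sum(np.mean((o - np.asarray(t, dtype=np.float64)) ** 2) for t in targets))
    if kind == "cross_entropy":
        if o.ndim != 3:
            raise ValueError("cross entropy expects (K+1, H, W) probabilities")
        total = 0.0
        for t in targets:
            t = np.asarray(t, dtype=np.intp)
            picked = np.take_along_axis(o, t[None], axis=0)[0]
            total += float(np.mean(-np.log(np.clip(picked, _EPS, 1.0))))
        return total
    raise ValueError(f"unknown loss kind {kind!r}")


def split_with_embedded_validation(
    dataset: list, fraction: float, seed: int
) -> tuple[list, list]:
    """Split where the validation subset stays inside the training set.

    Returns ``(training, validation)`` with ``training == dataset`` (every
    image is trained on) and ``validation`` a seeded random subset of it.
    """
    n = len(dataset)
    n_val = int(n * fraction)
    if n_val < 1:
        raise ValueError(
            f"validation fraction {fraction} yields no validation images for n={n}"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=n_val, replace=False).tolist())
    return list(dataset), [dataset[i] for i in idx]


def _loss_and_grad(
    model: SegModel, x: np.ndarray, targets: list[np.ndarray], kind: str
) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient w.r.t. the logits (training mode)."""
    logits = model.forward(x, train=True)
    n, _, h, w = logits.shape
    m = n * h * w
    if kind == "mse":
        o = 1.0 / (1.0 + np.exp(-logits))
        loss, do = 0.0, np.zeros_like(o)
        for t in targets:
            diff = o - t[:, None]
            loss += float(np.mean(diff ** 2) * (diff.size / m))  # per-image pixel mean
            do += 2.0 * diff / m
        dlogits = (do * o * (1.0 - o)).astype(np.float32)
        return loss, dlogits
    # cross entropy over channel softmax
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    o = e / e.sum(axis=1, keepdims=True)
    loss = 0.0
    dlogits = np.zeros_like(o)
    for t in targets:
        onehot_idx = t[:, None].astype(np.intp)
        picked = np.take_along_axis(o, onehot_idx, axis=1)[:, 0]
        loss += float(np.mean(-np.log(np.clip(picked, _EPS, 1.0))))
        d = o.copy()
        np.put_along_axis(
            d, onehot_idx,
            np.take_along_axis(d, onehot_idx, axis=1) - 1.0, axis=1,
        )
        dlogits += d / m
    return loss, dlogits.astype(np.float32)


def _resolve_loss_kind(cfg: TrainConfig, model: SegModel) -> str:
    if cfg.loss_kind != "auto":
        return cfg.loss_kind
    return "mse" if model.cfg.out_channels == 1 else "cross_entropy"


def _validation_scores(
    model: SegModel, val: list[TrainSample], threshold: float, n_classes: int
) -> tuple[float, float]:
    preds = [predict_mask(model, s.image, threshold) for s in val]
    fines = [s.fine_label for s in val]
    if any(f is None for f in fines):
        raise ValueError("validation samples need fine labels")
    val_miou = evaluate_dataset(preds, fines, n_classes).miou
    mgrls = [s.mgrl if s.mgrl is not None else s.targets[0] for s in val]
    mgrl_sim = evaluate_dataset(preds, mgrls, n_classes).miou
    return float(val_miou), float(mgrl_sim)


def train(
    model: SegModel, samples: list[TrainSample], cfg: TrainConfig
) -> tuple[SegModel, TrainingHistory]:
    """Optimize the coarse-label-pair loss and track the endpoint per epoch.

    Inputs are normalized to [0, 1]; batches are reshuffled each epoch from
    the run seed; partial final batches are kept.  Checkpoints retained:
    best validation mIOU so far and the last epoch.  Returns the model at
    its *last* state (use ``history.best_state`` to restore the endpoint).
    """
    if not samples:
        raise ValueError("no training samples")
    kind = _resolve_loss_kind(cfg, model)
    n_classes = model.cfg.n_classes
    xs = [image_to_input(s.image) for s in samples]
    if kind == "mse":
        tgt = [[np.asarray(t, dtype=np.float32) for t in s.targets] for s in samples]
    else:
        tgt = [[np.asarray(t, dtype=np.intp) for t in s.targets] for s in samples]
    n_targets = len(samples[0].targets)
    if any(len(t) != n_targets for t in tgt):
        raise ValueError("all samples must carry the same number of targets")

    _, val = split_with_embedded_validation(samples, cfg.validation_fraction, cfg.seed)
    opt = model.make_optimizer(cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    best_miou = -1.0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        total, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            x = np.stack([xs[i] for i in batch])
            bt = [np.stack([tgt[i][j] for i in batch]) for j in range(n_targets)]
            opt.zero_grad()
            loss, dlogits = _loss_and_grad(model, x, bt, kind)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}; "
                    "lower the learning rate or check the targets"
                )
            model.backward(dlogits)
            opt.step()
            total += loss * len(batch)
            seen += len(batch)
        val_miou, mgrl_sim = _validation_scores(
            model, val, cfg.prediction_threshold, n_classes
        )
        history.records.append(
            EpochRecord(epoch, total / seen, val_miou, mgrl_sim)
        )
        if val_miou > best_miou:
            best_miou = val_miou
            history.best_state = model.clone_state()
        history.last_state = model.clone_state()
    return model, history


def select_endpoint(history: TrainingHistory) -> int:
    """The training endpoint: epoch of maximum validation mIOU (earliest tie)."""
    return history.best_epoch


def generate_plfl(
    model: SegModel, images: list[np.ndarray], threshold: float = 0.7
) -> list[np.ndarray]:
    """Pixel-level fine labels for every image (training images included —
    labelling the whole set is the point of the exercise)."""
    return [predict_mask(model, img, threshold) for img in images]
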