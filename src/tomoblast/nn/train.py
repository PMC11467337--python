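"""Training recipe for the volumetric genotype classifier.

The published optimization protocol, reproduced at configurable scale:
Adam (first/second moment decays 0.5 / 0.999) with initial learning rate
5e-4, decoupled weight decay 1e-4, cosine-annealed learning rate with a
32-epoch period, batch size 16, and cross-entropy weighted inversely to the
class sizes of the training set.  Each epoch feeds every training image
twice -- once as-is and once randomly augmented.  Gradient updates use the
*optimization* split only; the *generalization* split (a held-out portion of
the training patients) is evaluated each epoch, and the selected checkpoint
maximizes (training accuracy + generalization accuracy).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentParams, augment_volume
from .layers import Adam
from .network import ArchConfig, TomoNet

__all__ = ["TrainConfig", "PredictionRecord", "class_weights",
           "weighted_cross_entropy", "cosine_lr", "train", "predict",
           "predict_batch", "save_checkpoint", "load_checkpoint"]

#: Genotype class order of the two output units.
CLASSES = ("WT", "MUT")


@dataclass
class TrainConfig:
    lr0: float = 5e-4
    weight_decay: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    cosine_period: int = 32          # epochs per annealing cycle
    batch_size: int = 16
    epochs: int = 200
    augment: AugmentParams = field(default_factory=AugmentParams)
    seed: int = 0

    def validate(self):
        if not (0 < self.lr0 and 0 <= self.weight_decay):
            raise ValueError("invalid optimizer settings")
        if self.epochs < 1 or self.epochs > 200:
            raise ValueError("epochs must lie in [1, 200]")
        if self.batch_size < 1 or self.cosine_period < 1:
            raise ValueError("batch_size and cosine_period must be >= 1")


@dataclass
class PredictionRecord:
    image_id: str
    out_wt: float
    out_mut: float
    predicted_label: str
    latent: np.ndarray


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class loss weights inversely proportional to class counts.

    Normalized so balanced classes give weight 1 each (the weighted loss then
    reduces to the plain cross-entropy).
    """
    labels = np.asarray(labels)
    counts = np.array([(labels == c).sum() for c in range(2)], dtype=np.float64)
    if (counts == 0).any():
        raise ValueError("training data must contain both classes")
    return counts.sum() / (2.0 * counts)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy; returns (loss, dL/dlogits).

    ``loss = sum_i w_{y_i} * (-log softmax(z_i)_{y_i}) / sum_i w_{y_i}``
    (the weighted mean, so the magnitude is comparable across batch
    compositions).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    wi = weights[labels]
    wsum = wi.sum()
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    loss = float((wi * nll).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (wi / wsum)[:, None]
    return loss, grad.astype(np.float32)


def cosine_lr(epoch: int, lr0: float, period: int) -> float:
    """Cosine annealing with warm restarts every ``period`` epochs."""
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * (epoch % period) / period))


def _accuracy(model: TomoNet, images, labels, batch: int) -> float:
    correct = 0
    for i in range(0, len(images), batch):
        out = model.forward(images[i:i + batch], training=False)
        # tie-breaking toward WT: predict MUT only on a strictly larger score
        pred = (out[:, 1] > out[:, 0]).astype(int)
        correct += int((pred == labels[i:i + batch]).sum())
    return correct / len(images)


def train(images: np.ndarray, labels: np.ndarray, split: np.ndarray,
          arch: ArchConfig, config: TrainConfig | None = None,
          progress: bool = False):
    """Train the classifier; returns ``(model, history)``.

    Parameters
    ----------
    images
        (N, D, H, W) float array, already normalized (medium-subtracted).
    labels
        Integer classes (0 = WT, 1 = MUT) or "WT"/"MUT" strings.
    split
        Per-image "optimization" / "generalization" assignment; gradient
        steps use the optimization subset only.
    """
    import pandas as pd

    config = config or TrainConfig()
    config.validate()
    labels = np.asarray([CLASSES.index(l) if isinstance(l, str) else int(l)
                         for l in labels])
    split = np.asarray(split)
    images = np.asarray(images, dtype=np.float32)
    opt_idx = np.nonzero(split == "optimization")[0]
    gen_idx = np.nonzero(split == "generalization")[0]
    if len(opt_idx) == 0:
        raise ValueError("no optimization images")
    if len(np.unique(labels[opt_idx])) < 2:
        raise ValueError("optimization set contains a single class")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_epochs = [np.random.default_rng(s) for s in ss.spawn(2)]
    model = TomoNet(arch, rng_init)
    opt = Adam(model.layers, lr=config.lr0, beta1=config.adam_beta1,
               beta2=config.adam_beta2, weight_decay=config.weight_decay)
    w = class_weights(labels[opt_idx])

    hist = []
    best = (-np.inf, None, None)  # (score, epoch, state)
    it = range(config.epochs)
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(it, desc="training")
        except ImportError:
            pass
    for epoch in it:
        rng = np.random.default_rng(rng_epochs.integers(2 ** 31))
        lr = cosine_lr(epoch, config.lr0, config.cosine_period)
        # every training image twice per epoch: original and augmented.
        # Batches are stratified by class (proportional interleave of the
        # per-class shuffles): at small cohort sizes, class-imbalanced
        # batches otherwise drive a noisy random walk of the output bias
        # that swamps the early discriminative signal.
        per_class = []
        for cls in np.unique(labels[opt_idx]):
            cls_idx = opt_idx[labels[opt_idx] == cls]
            s = [(i, False) for i in cls_idx] + [(i, True) for i in cls_idx]
            per_class.append([s[j] for j in rng.permutation(len(s))])
        samples = []
        counts = [len(s) for s in per_class]
        taken = [0] * len(per_class)
        for _ in range(sum(counts)):
            c = int(np.argmax([(n - t) / n for n, t in zip(counts, taken)]))
            samples.append(per_class[c][taken[c]])
            taken[c] += 1
        losses = []
        for b0 in range(0, len(samples), config.batch_size):
            sel = samples[b0:b0 + config.batch_size]
            xb = np.stack([
                augment_volume(images[i], config.augment, rng) if aug else images[i]
                for i, aug in sel
            ])
            yb = np.array([labels[i] for i, _ in sel])
            opt.zero_grad()
            out = model.forward(xb, training=True)
            loss, dout = weighted_cross_entropy(out, yb, w)
            model.backward(dout)
            opt.step(lr=lr)
            losses.append(loss)
        opt_acc = _accuracy(model, images[opt_idx], labels[opt_idx], config.batch_size)
        gen_acc = (_accuracy(model, images[gen_idx], labels[gen_idx], config.batch_size)
                   if len(gen_idx) else np.nan)
        score = opt_acc + (gen_acc if np.isfinite(gen_acc) else 0.0)
        if score > best[0]:
            best = (score, epoch, {k: v.copy() for k, v in model.state_dict().items()})
        hist.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)),
                     "opt_acc": opt_acc, "gen_acc": gen_acc})

    model.load_state_dict(best[2])
    history = pd.DataFrame(hist)
    history["selected"] = history["epoch"] == best[1]
    return model, history


def predict_batch(model: TomoNet, images: np.ndarray, image_ids=None) -> list[PredictionRecord]:
    """Deterministic inference; ties (equal raw outputs) are called WT so that
    the screen errs toward confirmatory genetic testing."""
    images = np.asarray(images, dtype=np.float32)
    if image_ids is None:
        image_ids = [str(i) for i in range(len(images))]
    out = []
    for i in range(0, len(images), 16):
        scores = model.forward(images[i:i + 16], training=False)
        latents = model.latent
        for j in range(len(scores)):
            o_wt, o_mut = float(scores[j, 0]), float(scores[j, 1])
            label = "MUT" if o_mut > o_wt else "WT"
            out.append(PredictionRecord(image_id=str(image_ids[i + j]), out_wt=o_wt,
                                        out_mut=o_mut, predicted_label=label,
                                        latent=np.array(latents[j])))
    return out


def predict(model: TomoNet, volume: np.ndarray, image_id: str = "0") -> PredictionRecord:
    """Single-volume inference (see :func:`predict_batch` for the tie rule)."""
    volume = np.asarray(volume, dtype=np.float32)
    if volume.shape != tuple(model.arch.input_shape):
        raise ValueError(
            f"volume shape {volume.shape} != model input {model.arch.input_shape}"
        )
    return predict_batch(model, volume[None], [image_id])[0]


def save_checkpoint(path, model: TomoNet, config: TrainConfig | None = None) -> Path:
    """Single-file checkpoint: parameters + architecture + training config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"arch": asdict(model.arch),
            "train": asdict(config) if config else None}
    if meta["train"] is not None:
        meta["train"]["augment"] = asdict(config.augment)
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **model.state_dict())
    return path


def load_checkpoint(path) -> tuple[TomoNet, TrainConfig | None]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arch = ArchConfig(**{**meta["arch"],
                             "input_shape": tuple(meta["arch"]["input_shape"])})
        model = TomoNet(arch, rng=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    cfg = None
    if meta.get("train"):
        t = dict(meta["train"])
        aug = t.pop("augment", None)
        cfg = TrainConfig(**{**t, "augment": AugmentParams(
            **{**aug, "max_translation": tuple(aug["max_translation"]),
               "flip_axes": tuple(aug["flip_axes"])}) if aug else AugmentParams()})
    return model, cfg
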