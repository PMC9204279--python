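"""Training, inference and evaluation entry points.

Defaults follow the study protocol for the full-scale model: batch size 2,
120 epochs, 512x512 inputs, Adam with an initial learning rate of 2e-4
decayed exponentially by a factor of 0.96 every 300 optimizer steps
(staircase).  The loss is the soft Dice loss; the best-validation-DSC
checkpoint is kept.  Everything is seeded, so a run is reproducible
bit-for-bit on CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats, metrics, preprocessing
from .model import ModelConfig, MSFAUNet, build_model
from .nn.autodiff import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "MetricReport",
    "lr_schedule",
    "Adam",
    "load_phantom_dataset",
    "train",
    "predict",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    batch_size: int = 2
    epochs: int = 120
    image_size: int = 512
    initial_lr: float = 2e-4
    decay_steps: int = 300
    decay_rate: float = 0.96
    optimizer: str = "adam"
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    augment: bool = True
    rotation_range: float = 15.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    shear_range: float = 8.0
    flip_prob: float = 0.5

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0 < self.decay_rate <= 1:
            raise ValueError(f"decay_rate must be in (0, 1], got {self.decay_rate}")
        self.model.validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["zoom_range"] = list(self.zoom_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["model"] = ModelConfig(**d.get("model", {}))
        if "zoom_range" in d:
            d["zoom_range"] = tuple(d["zoom_range"])
        return cls(**d)


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Staircase exponential decay: lr = lr0 * rate ** floor(step / decay_steps)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.initial_lr * cfg.decay_rate ** (step // cfg.decay_steps)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


# ---------------------------------------------------------------------------
# data loading

def load_phantom_dataset(data_dir, window=None, clahe: bool = True):
    """Load a generated phantom dataset into preprocessed arrays.

    Returns (case_ids, images, masks) with images (N, 1, H, W) in [0, 1] and
    masks (N, 1, H, W) binary.
    """
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    ids, imgs, masks = [], [], []
    for case in manifest["cases"]:
        ct = io_formats.read_dicom_slice(data_dir / case["image_path"])
        hu = preprocessing.pixels_to_hu(ct.stored_pixels, ct.rescale_slope,
                                        ct.rescale_intercept)
        imgs.append(preprocessing.preprocess_slice(hu, window, clahe=clahe))
        masks.append(io_formats.read_mask_png(data_dir / case["mask_path"]))
        ids.append(case["case_id"])
    images = np.stack(imgs)[:, None].astype(np.float32)
    targets = np.stack(masks)[:, None].astype(np.float32)
    return ids, images, targets


# ---------------------------------------------------------------------------
# training

def _epoch_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _val_dsc(model: MSFAUNet, images, targets, threshold=0.5) -> float:
    model.eval()
    vals = []
    for i in range(images.shape[0]):
        prob = model(images[i:i + 1]).data
        pred = (prob[0, 0] >= threshold).astype(np.uint8)
        dsc, _, _, _ = metrics.overlap_metrics(
            metrics.confusion_counts(pred, targets[i, 0].astype(np.uint8)))
        vals.append(dsc)
    model.train()
    return float(np.mean(vals))


def train(cfg: TrainConfig, train_data, val_data, out_dir=None,
          log_every: int = 0) -> dict:
    """Optimize the model on (images, targets) tuples; keep the best-val-DSC
    weights.

    train_data / val_data: (images, targets) arrays as produced by
    `load_phantom_dataset`.  Returns a history dict with per-epoch train loss
    and validation DSC plus the trained model (under key "model").
    """
    cfg.validate()
    tr_x, tr_y = train_data
    va_x, va_y = val_data
    if tr_x.shape[0] == 0 or va_x.shape[0] == 0:
        raise ValueError("empty train or validation split")
    model = build_model(cfg.model)
    opt = Adam(model.parameters())
    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(cfg.seed + 1)
    history = {"train_loss": [], "val_dsc": [], "lr": []}
    best = {"val_dsc": -1.0, "state": None, "epoch": -1}
    step = 0
    model.train()
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _epoch_batches(tr_x.shape[0], cfg.batch_size, rng):
            xb = tr_x[idx]
            yb = tr_y[idx]
            if cfg.augment:
                xb = xb.copy()
                yb = yb.copy()
                for b in range(xb.shape[0]):
                    spec = preprocessing.sample_augment_spec(
                        aug_rng, cfg.rotation_range, cfg.zoom_range,
                        cfg.shear_range, cfg.flip_prob)
                    xi, mi = preprocessing.augment_pair(xb[b, 0], yb[b, 0], spec)
                    xb[b, 0] = xi
                    yb[b, 0] = mi
            model.zero_grad()
            out = model(xb)
            loss = metrics.dice_loss(out, yb, eps=1.0)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at step {step}")
            loss.backward()
            opt.step(lr_schedule(step, cfg))
            losses.append(float(loss.data))
            step += 1
        val_dsc = _val_dsc(model, va_x, va_y)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dsc"].append(val_dsc)
        history["lr"].append(lr_schedule(step, cfg))
        if val_dsc > best["val_dsc"]:
            best = {"val_dsc": val_dsc, "state": model.state_dict(),
                    "epoch": epoch}
        if log_every and (epoch + 1) % log_every == 0:
            logger.info("epoch %d: train loss %.4f, val DSC %.4f",
                        epoch + 1, history["train_loss"][-1], val_dsc)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_val_dsc"] = best["val_dsc"]
    history["model"] = model
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "best.npz")
        cfg.to_yaml(out_dir / "train_config.yaml")
        with open(out_dir / "history.json", "w") as fh:
            json.dump({k: v for k, v in history.items() if k != "model"}, fh)
    return history


def save_checkpoint(model: MSFAUNet, path) -> None:
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> MSFAUNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
        model = build_model(cfg)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    model.eval()
    return model


def predict(model: MSFAUNet, images, threshold: float = 0.5) -> np.ndarray:
    """Forward pass in inference mode -> binary masks (N, H, W) uint8."""
    model.eval()
    masks = []
    for i in range(images.shape[0]):
        prob = model(images[i:i + 1]).data[0, 0]
        masks.append((prob >= threshold).astype(np.uint8))
    return np.stack(masks)


# ---------------------------------------------------------------------------
# evaluation / reporting

@dataclass
class MetricReport:
    case_ids: list[str]
    per_case: list[metrics.MetricVector]
    mean: dict
    std: dict
    boxplot: dict

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(
            [{"case_id": cid, "dsc": m.dsc, "jsc": m.jsc, "ppv": m.ppv,
              "se": m.se, "hd": m.hd}
             for cid, m in zip(self.case_ids, self.per_case)]
        ).to_csv(path, index=False)

    def summary_table(self) -> str:
        lines = ["metric  mean ± std"]
        for k in ("dsc", "jsc", "ppv", "se", "hd"):
            lines.append(f"{k.upper():4s}  {self.mean[k]:.2f} ± {self.std[k]:.2f}")
        return "\n".join(lines)


def _boxplot_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "outliers": [float(v) for v in values[(values < lo_fence)
                                              | (values > hi_fence)]],
    }


def evaluate(pred_masks, target_masks, case_ids=None,
             spacing=(1.0, 1.0)) -> MetricReport:
    """Per-case metrics plus mean ± std and box-plot summaries.

    NaN entries (undefined PPV/SE) and infinite HD are excluded from the
    aggregates but kept in the per-case list.
    """
    n = len(pred_masks)
    if n != len(target_masks):
        raise ValueError(f"{n} predictions vs {len(target_masks)} targets")
    case_ids = list(case_ids) if case_ids is not None else \
        [f"case_{i:04d}" for i in range(n)]
    per_case = [metrics.evaluate_pair(pred_masks[i], target_masks[i], spacing)
                for i in range(n)]
    mean, std, box = {}, {}, {}
    for k in ("dsc", "jsc", "ppv", "se", "hd"):
        vals = np.array([getattr(m, k) for m in per_case], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean[k] = float(vals.mean()) if vals.size else float("nan")
        std[k] = float(vals.std(ddof=0)) if vals.size else float("nan")
        box[k] = _boxplot_stats(vals) if vals.size else {}
    return MetricReport(case_ids, per_case, mean, std, box)
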