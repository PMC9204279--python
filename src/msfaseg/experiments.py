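"""Canned desk-scale experiments on synthetic phantoms.

Two studies, both fully seeded:

``overfit_study``
    Capacity check: a small model (3 levels, 8 base channels) memorizes four
    noise-free 64x64 phantoms.  Uses a higher constant learning rate (3e-3)
    than the full protocol — appropriate for 4-sample memorization — and no
    augmentation.

``phantom_study``
    The study protocol end to end at phantom scale: generate 80 phantoms,
    split 6:1:1 by case into 60/10/10, train the small model with the
    protocol's optimizer settings (batch 2, Adam, lr 2e-4 with staircase
    exponential decay 0.96 / 300 steps) and augmentation, keep the
    best-validation checkpoint, and evaluate DSC/JSC/PPV/SE/HD on the 10
    held-out test phantoms.  Image size 64 and 25 epochs keep the run at
    CPU scale; validation DSC has plateaued by then.
"""

from __future__ import annotations

import numpy as np

from . import io_formats, metrics
from .model import ModelConfig, build_model
from .phantom import PhantomConfig, generate_phantom
from .preprocessing import preprocess_slice
from .training import Adam, TrainConfig, evaluate, predict, train

__all__ = ["overfit_study", "phantom_study", "load_phantom_arrays"]


def load_phantom_arrays(cfg: PhantomConfig, n: int):
    """Generate n phantoms in memory and preprocess them for the model."""
    imgs, msks = [], []
    for i in range(n):
        pair = generate_phantom(cfg, i)
        imgs.append(preprocess_slice(pair.image))
        msks.append(pair.mask)
    x = np.stack(imgs)[:, None].astype(np.float32)
    y = np.stack(msks)[:, None].astype(np.float32)
    return x, y


def overfit_study(seed: int = 0, steps: int = 300, lr: float = 3e-3,
                  n: int = 4, image_size: int = 64) -> dict:
    """Memorize `n` noise-free phantoms; report final loss / train DSC and
    whether every parameter tensor received a gradient at some step."""
    pcfg = PhantomConfig(image_size=image_size, vessel_count=0, noise_sd=0.0,
                         seed=seed)
    x, y = load_phantom_arrays(pcfg, n)
    model = build_model(ModelConfig(num_levels=3, base_channels=8, seed=seed))
    opt = Adam(model.parameters())
    rng = np.random.default_rng(seed)
    params = model.parameters()
    got_grad = np.zeros(len(params), dtype=bool)
    for step in range(steps):
        idx = rng.permutation(n)[:2]
        model.zero_grad()
        loss = metrics.dice_loss(model(x[idx]), y[idx])
        loss.backward()
        for i, p in enumerate(params):
            if not got_grad[i] and p.grad is not None and np.any(p.grad != 0):
                got_grad[i] = True
        opt.step(lr)
    model.zero_grad()
    final_loss = float(metrics.dice_loss(model(x), y).data)
    preds = predict(model, x)
    dscs = [metrics.overlap_metrics(
        metrics.confusion_counts(preds[i], y[i, 0].astype(np.uint8)))[0]
        for i in range(n)]
    return {
        "final_train_loss": final_loss,
        "train_dsc": float(np.mean(dscs)),
        "all_params_received_grad": bool(got_grad.all()),
        "n_params": len(params),
    }


def phantom_study(seed: int = 0, n: int = 80, image_size: int = 64,
                  epochs: int = 25) -> dict:
    """Full pipeline at phantom scale; returns the metric report and history."""
    pcfg = PhantomConfig(image_size=image_size, seed=seed)
    x, y = load_phantom_arrays(pcfg, n)
    ids = [f"phantom_{i:04d}" for i in range(n)]
    split = io_formats.split_dataset(ids, (6, 1, 1), seed=seed)
    pos = {c: i for i, c in enumerate(ids)}
    tr = [pos[c] for c in split.train]
    va = [pos[c] for c in split.validation]
    te = [pos[c] for c in split.test]
    tcfg = TrainConfig(batch_size=2, epochs=epochs, image_size=image_size,
                       seed=seed,
                       model=ModelConfig(num_levels=3, base_channels=8,
                                         seed=seed))
    history = train(tcfg, (x[tr], y[tr]), (x[va], y[va]))
    model = history.pop("model")
    preds = predict(model, x[te])
    report = evaluate(preds, y[te][:, 0].astype(np.uint8),
                      case_ids=[ids[i] for i in te])
    return {
        "report": report,
        "history": history,
        "split_sizes": (len(tr), len(va), len(te)),
        "model": model,
        "test_inputs": (x[te], y[te]),
    }
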