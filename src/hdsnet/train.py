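"""Training, evaluation, sparsity sweep, prediction, checkpointing.

Optimization follows the reference protocol: SGD with initial learning rate
0.01, momentum 0.9, weight decay 1e-4, batch size 24, 300 epochs, no learning
rate schedule and no data augmentation. Every source of randomness (weight
init, minibatch shuffling, Bernoulli mask draws) flows from explicit seeds, so
a run is bit-reproducible on one CPU.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import DatasetIndex, load_batch, load_image, save_mask
from .losses import combined_loss_with_grad, sigmoid
from .metrics import evaluate_pair
from .model import HDSNet, ModelConfig, build_model
from .nn import SGD

__all__ = [
    "TrainConfig",
    "save_checkpoint",
    "load_checkpoint",
    "train",
    "evaluate",
    "write_report",
    "sweep_sparse_ratio",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    optimizer: str = "sgd"
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 24
    epochs: int = 300
    seed: int = 0
    max_steps: int | None = None  # cap on optimizer steps (desk-scale runs)
    device: str = "cpu"

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr must be >= 0 and batch_size/epochs >= 1")
        if self.optimizer != "sgd":
            raise ValueError(f"only 'sgd' is implemented, got {self.optimizer!r}")
        if self.device != "cpu":
            raise ValueError("only CPU execution is supported")

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(model_cfg: ModelConfig, train_cfg: TrainConfig) -> str:
    blob = json.dumps({"model": model_cfg.to_dict(), "train": train_cfg.to_dict()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: HDSNet, path, extra: dict | None = None):
    """Single-file .npz archive: all weights + the model config as JSON."""
    state = model.state_dict()
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> HDSNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(ModelConfig.from_dict(meta["config"]), seed=0)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: HDSNet, records, input_size=None, threshold=None) -> dict:
    """Per-image Dice/IoU/Sen/Spe (image-averaged summary), eval-mode forwards."""
    input_size = input_size or model.cfg.input_size
    threshold = threshold if threshold is not None else model.cfg.threshold
    model.eval()
    rows = []
    for r in records:
        img, msk = load_batch([r], input_size)
        probs = sigmoid(model.forward(img))[0, 0]
        pred = probs > threshold
        row = {"id": r.id, **evaluate_pair(pred, msk[0, 0] > 0.5)}
        rows.append(row)
    summary = {
        "id": "mean",
        **{k: float(np.mean([row[k] for row in rows])) if rows else float("nan")
           for k in ("iou", "sen", "spe", "dice")},
    }
    return {"rows": rows, "summary": summary}


def write_report(report: dict, out_prefix):
    """Write the evaluation report as CSV (per-image + summary row) and JSON."""
    out_prefix = Path(out_prefix)
    fields = ["id", "iou", "sen", "spe", "dice"]
    with open(out_prefix.with_suffix(".csv"), "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=fields)
        wr.writeheader()
        for row in report["rows"]:
            wr.writerow({k: row[k] for k in fields})
        wr.writerow({k: report["summary"][k] for k in fields})
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(report, fh, indent=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model_cfg: ModelConfig, train_cfg: TrainConfig, index: DatasetIndex,
          out_dir=None, eval_each_epoch: bool = True) -> dict:
    """Minibatch SGD on the Dice+BCE compound loss.

    Returns a history dict; if ``out_dir`` is given, writes the best-Dice
    checkpoint (``best.npz``), the final checkpoint and a machine-readable
    training log.
    """
    train_records = index.train
    if not train_records:
        raise ValueError("empty train split — run split() on the index first")
    test_records = index.test

    model = build_model(model_cfg, seed=train_cfg.seed)
    mask_rng = np.random.default_rng(train_cfg.seed + 1)
    model.dsa.set_rng(mask_rng)
    shuffle_rng = np.random.default_rng(train_cfg.seed + 2)
    opt = SGD(model.parameters(), lr=train_cfg.lr, momentum=train_cfg.momentum,
              weight_decay=train_cfg.weight_decay)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    history = {
        "config_hash": _config_hash(model_cfg, train_cfg),
        "seed": train_cfg.seed,
        "epochs": [],
        "steps": [],
    }
    best_dice = -1.0
    step = 0
    n = len(train_records)
    bs = min(train_cfg.batch_size, n)
    input_size = model_cfg.input_size
    stop = False

    for epoch in range(train_cfg.epochs):
        order = shuffle_rng.permutation(n)
        model.train()
        epoch_losses = []
        for start in range(0, n, bs):
            batch = [train_records[i] for i in order[start : start + bs]]
            imgs, msks = load_batch(batch, input_size)
            logits = model.forward(imgs)
            loss, grad = combined_loss_with_grad(logits, msks)
            if not np.isfinite(loss.total):
                raise RuntimeError(
                    f"non-finite loss at step {step}: total={loss.total} "
                    f"(dice={loss.dice_term}, bce={loss.bce_term})"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss.total)
            history["steps"].append({"step": step, "loss": loss.total})
            step += 1
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                stop = True
                break
        entry = {"epoch": epoch, "loss": float(np.mean(epoch_losses))}
        if eval_each_epoch and test_records:
            rep = evaluate(model, test_records, input_size)
            entry.update({k: rep["summary"][k] for k in ("dice", "iou", "sen", "spe")})
            if entry["dice"] > best_dice:
                best_dice = entry["dice"]
                if out_dir is not None:
                    save_checkpoint(model, out_dir / "best.npz",
                                    extra={"epoch": epoch, "dice": best_dice})
        history["epochs"].append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if stop:
            break

    history["best_dice"] = best_dice
    if out_dir is not None:
        save_checkpoint(model, out_dir / "final.npz", extra={"steps": step})
        if best_dice < 0:  # no eval ran; make best == final
            save_checkpoint(model, out_dir / "best.npz", extra={"steps": step})
        with open(out_dir / "history.json", "w") as fh:
            json.dump(history, fh, indent=1)
    history["model"] = model
    return history


# ---------------------------------------------------------------------------
# sparsity-ratio sweep
# ---------------------------------------------------------------------------

def sweep_sparse_ratio(ratios, model_cfg: ModelConfig, train_cfg: TrainConfig,
                       index: DatasetIndex, out_csv=None) -> list:
    """Train/evaluate one model per Bernoulli keep-ratio; tabulate Dice/IoU.

    Reproduces the ablation protocol shape (ratio × overlap metrics) at
    whatever scale the supplied configs define.
    """
    rows = []
    for ratio in ratios:
        cfg_r = ModelConfig.from_dict({**model_cfg.to_dict(), "sparse_ratio": float(ratio)})
        hist = train(cfg_r, train_cfg, index, out_dir=None, eval_each_epoch=False)
        records = index.test or index.train
        rep = evaluate(hist["model"], records, cfg_r.input_size)
        rows.append({"sparse_ratio": float(ratio),
                     "dice": rep["summary"]["dice"], "iou": rep["summary"]["iou"]})
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["sparse_ratio", "dice", "iou"])
            wr.writeheader()
            wr.writerows(rows)
    return rows


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: HDSNet, image_paths, out_dir) -> list:
    """Binary PNG masks at each image's original resolution.

    The probability map is resized back to the source size bilinearly before
    thresholding, so mask edges stay smooth.
    """
    from PIL import Image as PILImage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model.eval()
    written = []
    for p in image_paths:
        p = Path(p)
        with PILImage.open(p) as im:
            orig = im.size  # (W, H)
        img = load_image(p, model.cfg.input_size)[None]
        probs = sigmoid(model.forward(img))[0, 0]
        pm = PILImage.fromarray((probs * 255).astype(np.uint8)).resize(orig, PILImage.BILINEAR)
        pred = np.asarray(pm, dtype=np.float32) / 255.0 > model.cfg.threshold
        out_path = out_dir / f"{p.stem}_segmentation.png"
        save_mask(pred, out_path)
        written.append(out_path)
    return written
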