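"""Training loop, poly learning-rate schedule, checkpointing and evaluation.

The optimizer is Adam with β1 = 0.90 ("momentum"), weight decay 1e-4
(coupled, added to the gradient) and initial learning rate 3e-4, decayed per
step by the poly policy

    lr = lr_init * (1 - iter / max_iter) ** power,   power = 0.9.

Model selection is by best mean validation DSC over the three subregions.
All randomness (parameter init, shuffling) derives from one config seed, so
CPU runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .io_preprocess import SlicePair
from .losses import LossConfig, total_loss
from .metrics import MetricsReport, evaluate_set
from .model import MAFFResUNet, ModelConfig
from .nn import Adam


@dataclass
class TrainConfig:
    lr_init: float = 3e-4
    momentum_beta1: float = 0.90
    weight_decay: float = 1e-4
    power: float = 0.9
    batch_size: int = 16
    max_iter: int = 200
    seed: int = 0
    checkpoint_every: int = 50
    threshold: float = 0.5
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.lr_init <= 0:
            raise ValueError("lr_init must be > 0")
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if self.batch_size < 1 or self.max_iter < 1:
            raise ValueError("batch_size and max_iter must be >= 1")


@dataclass
class TrainState:
    step: int = 0
    current_lr: float = 0.0
    best_val_dsc: float = -np.inf
    history: list[dict] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def poly_lr(lr_init: float, iter: int, max_iter: int, power: float) -> float:
    """Poly decay lr_init · (1 − iter/max_iter)^power; strictly decreasing."""
    if not 0 <= iter <= max_iter:
        raise ValueError(f"iter {iter} outside [0, {max_iter}]")
    return lr_init * (1.0 - iter / max_iter) ** power


def _batch_arrays(pairs: list[SlicePair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in pairs]).astype(np.float64)
    targets = np.stack([p.target for p in pairs]).astype(np.float64)
    return images, targets


def _mean_val_dsc(report: MetricsReport) -> float:
    values = [report.mean[r]["dsc"] for r in ("WT", "TC", "ET")
              if "dsc" in report.mean.get(r, {})]
    return float(np.mean(values)) if values else 0.0


def predict(model: MAFFResUNet, pairs: list[SlicePair],
            batch_size: int = 8) -> list[np.ndarray]:
    """Eval-mode forward over slices; returns per-slice probability maps."""
    model.eval()
    out: list[np.ndarray] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        images, _ = _batch_arrays(chunk)
        probs = model(Tensor(images)).data
        out.extend(probs[i] for i in range(len(chunk)))
    return out


def evaluate(model: MAFFResUNet, pairs: list[SlicePair],
             cfg: TrainConfig | None = None) -> MetricsReport:
    """Evaluate a model on preprocessed slices (threshold 0.5 by default)."""
    cfg = cfg or TrainConfig()
    if not pairs:
        raise ValueError("empty evaluation set")
    predictions = predict(model, pairs, batch_size=cfg.batch_size)
    targets = [p.target for p in pairs]
    return evaluate_set(predictions, targets, threshold=cfg.threshold)


def train(model: MAFFResUNet, train_slices: list[SlicePair],
          val_slices: list[SlicePair] | None, cfg: TrainConfig,
          out_dir: str | Path | None = None) -> TrainState:
    """Run ``cfg.max_iter`` Adam steps of the composite loss.

    Shuffles slices each epoch with a seeded RNG, applies the poly schedule
    every step, evaluates mean validation DSC every ``checkpoint_every``
    steps, and (if ``out_dir`` is given) writes latest/best checkpoints plus
    the history CSV.
    """
    if not train_slices:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr_init,
                     beta1=cfg.momentum_beta1,
                     weight_decay=cfg.weight_decay)
    state = TrainState()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(json.dumps(
            {"train": _config_dict(cfg), "model": asdict(model.config)},
            indent=1))

    order: list[int] = []
    for step in range(cfg.max_iter):
        if len(order) < cfg.batch_size:
            order = list(rng.permutation(len(train_slices)))
        batch_idx = [order.pop() for _ in range(
            min(cfg.batch_size, len(train_slices)))]
        images, targets = _batch_arrays([train_slices[i] for i in batch_idx])

        lr = poly_lr(cfg.lr_init, step, cfg.max_iter, cfg.power)
        optimizer.lr = lr
        model.train()
        model.zero_grad()
        probs = model(Tensor(images))
        loss = total_loss(probs, targets, cfg.loss)
        loss_value = loss.item()
        if not np.isfinite(loss_value):
            raise RuntimeError(f"non-finite loss {loss_value} at step {step}")
        loss.backward()
        optimizer.step()

        record = {"step": step, "lr": lr, "train_loss": loss_value,
                  "val_dsc": np.nan}
        last_step = step == cfg.max_iter - 1
        if val_slices and (
                (step + 1) % cfg.checkpoint_every == 0 or last_step):
            val_dsc = _mean_val_dsc(evaluate(model, val_slices, cfg))
            record["val_dsc"] = val_dsc
            if val_dsc > state.best_val_dsc:
                state.best_val_dsc = val_dsc
                if out_dir is not None:
                    model.save(out_dir / "best.npz",
                               extra={"step": step, "val_dsc": val_dsc})
        state.step = step + 1
        state.current_lr = lr
        state.history.append(record)

    if out_dir is not None:
        model.save(out_dir / "latest.npz", extra={"step": state.step})
        state.history_frame().to_csv(out_dir / "history.csv", index=False)
    return state


def _config_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d
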