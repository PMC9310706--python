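"""Training loop: plain SGD on the Bernoulli negative log-likelihood.

Protocol defaults mirror the study: batch size 1 (one bag per gradient
step), learning rate 1e-4, 500 epochs, no momentum, no weight decay, no
early stopping or schedule.  A "batch" of size b averages the per-bag losses
of b bags before stepping.  Bag order is reshuffled every epoch; everything
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bagging import PaddedBag
from .mil_models import MILModelConfig, forward, init_params, loss_and_grads

__all__ = ["TrainConfig", "train", "predict_padded", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; usually the learning rate is too high or the
    features were not standardized."""


@dataclass
class TrainConfig:
    """SGD hyperparameters (defaults are the study protocol)."""

    batch_size: int = 1
    learning_rate: float = 1e-4
    epochs: int = 500
    seed: int = 0
    momentum: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "seed": self.seed,
            "momentum": self.momentum,
            "weight_decay": self.weight_decay,
        }


def train(
    padded_bags: list[PaddedBag],
    model_cfg: MILModelConfig,
    train_cfg: TrainConfig,
    params: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Train on pre-padded bags; returns (parameters, per-epoch mean loss).

    With ``epochs=0`` the freshly initialized (or supplied) parameters are
    returned unchanged together with an empty loss curve.
    """
    if not padded_bags:
        raise ValueError("no training bags")
    sizes = {pb.n_slots for pb in padded_bags}
    if len(sizes) != 1:
        raise ValueError(f"all bags must be padded to the same size, got {sizes}")

    rng = np.random.default_rng(train_cfg.seed)
    if params is None:
        params = init_params(model_cfg, rng)
    else:
        params = {k: v.copy() for k, v in params.items()}

    labels = np.array([pb.label for pb in padded_bags])
    n = len(padded_bags)
    b = train_cfg.batch_size
    lr = train_cfg.learning_rate
    velocity = {k: np.zeros_like(v) for k, v in params.items()} if train_cfg.momentum else None

    loss_curve = np.empty(train_cfg.epochs)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, b):
            batch = order[start : start + b]
            grads_sum: dict[str, np.ndarray] | None = None
            batch_loss = 0.0
            for i in batch:
                loss, grads = loss_and_grads(
                    padded_bags[i], int(labels[i]), params, model_cfg,
                    train_mode=True, rng=rng,
                )
                batch_loss += loss
                if grads_sum is None:
                    grads_sum = grads
                else:
                    for k in grads_sum:
                        grads_sum[k] += grads[k]
            m = len(batch)
            epoch_loss += batch_loss
            if not np.isfinite(batch_loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}; lower the learning rate "
                    "or standardize the input features"
                )
            for k, g in grads_sum.items():
                step = g / m
                if train_cfg.weight_decay:
                    step = step + train_cfg.weight_decay * params[k]
                if velocity is not None:
                    velocity[k] = train_cfg.momentum * velocity[k] + step
                    step = velocity[k]
                params[k] -= lr * step
        loss_curve[epoch] = epoch_loss / n
    return params, loss_curve


def predict_padded(
    padded_bags: list[PaddedBag],
    params: dict[str, np.ndarray],
    model_cfg: MILModelConfig,
    threshold: float = 0.5,
):
    """Bag probabilities, hard labels (prob >= threshold -> 1) and attention.

    A probability exactly at the threshold is classified positive.
    """
    preds = [forward(pb, params, model_cfg, train_mode=False) for pb in padded_bags]
    probs = np.array([p.bag_prob for p in preds])
    labels = (probs >= threshold).astype(int)
    return probs, labels, preds
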