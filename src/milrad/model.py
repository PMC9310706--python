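"""Model / Results surface tying the pipeline together.

:class:`MILModel` is constructed from bags (or a per-nodule feature table)
and owns the preprocessing choices: leakage-free z-scoring, balanced
duplication padding, and optional synthetic-bag oversampling of the training
split.  ``fit`` runs SGD training and returns a :class:`MILResults` carrying
the fitted parameters, the loss curve, and prediction / attention /
persistence methods.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import oversampling as ovs
from .bagging import infer_max_bag_size, pad_bags
from .feature_io import FeatureScaler, dataframe_to_bags, read_feature_table
from .mil_models import MILModelConfig, MILPrediction
from .schema import Bag, DataError, FeatureSchema, default_schema
from .training import TrainConfig, predict_padded, train

__all__ = ["MILModel", "MILResults"]


class MILModel:
    """Attention-based (or mean/max-pooled) MIL classifier for nodule bags.

    Parameters
    ----------
    bags
        Training bags (one per subject).
    config
        Network architecture; defaults to the 103->64->32 attention model.
    max_bag_size
        Padding target; inferred from the training bags when omitted.
    schema
        Feature schema used for checkpoint integrity checks.
    """

    def __init__(
        self,
        bags: list[Bag],
        config: MILModelConfig | None = None,
        max_bag_size: int | None = None,
        schema: FeatureSchema | None = None,
    ):
        if not bags:
            raise DataError("MILModel needs at least one training bag")
        self.bags = bags
        self.schema = schema or default_schema()
        n_feat = bags[0].matrix.shape[1]
        self.config = config or MILModelConfig(input_dim=n_feat)
        if self.config.input_dim != n_feat:
            raise DataError(
                f"bags have {n_feat} features but config.input_dim is "
                f"{self.config.input_dim}"
            )
        self.max_bag_size = max_bag_size or infer_max_bag_size(bags)

    @classmethod
    def from_dataframe(cls, df, schema: FeatureSchema | None = None, **kwargs) -> "MILModel":
        schema = schema or default_schema()
        return cls(dataframe_to_bags(df, schema), schema=schema, **kwargs)

    @classmethod
    def from_table(cls, path: str | os.PathLike, schema: FeatureSchema | None = None, **kwargs) -> "MILModel":
        schema = schema or default_schema()
        return cls(read_feature_table(path, schema), schema=schema, **kwargs)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        oversample: ovs.OversampleConfig | None = None,
        **kwargs,
    ) -> "MILResults":
        """Standardize, oversample (training split only), pad, and train.

        Extra keyword arguments are forwarded to :class:`TrainConfig` when
        ``train_config`` is omitted.
        """
        train_cfg = train_config or TrainConfig(**kwargs)
        rng = np.random.default_rng(train_cfg.seed)

        train_bags = list(self.bags)
        n_real = len(train_bags)
        if oversample is not None and oversample.n_synthetic_negative > 0:
            pool = ovs.build_negative_pool(train_bags)
            neg_sizes = [len(b) for b in train_bags if b.label == 0]
            train_bags = train_bags + ovs.simulate_negative_bags(
                pool,
                oversample.n_synthetic_negative,
                self.max_bag_size,
                rng,
                cfg=oversample,
                negative_sizes=neg_sizes,
            )
        if oversample is not None and oversample.n_synthetic_positive > 0:
            positives = [b for b in self.bags if b.label == 1]
            full_pool = ovs.build_instance_pool(self.bags)
            train_bags = train_bags + ovs.simulate_positive_bags(
                positives,
                full_pool,
                oversample.n_synthetic_positive,
                self.max_bag_size,
                rng,
            )

        # scaler sees only the real training instances
        scaler = FeatureScaler.fit(self.bags)
        scaled = scaler.transform_bags(train_bags)
        padded = pad_bags(scaled, self.max_bag_size, rng)
        params, loss_curve = train(padded, self.config, train_cfg)
        return MILResults(
            model=self,
            params=params,
            loss_curve=loss_curve,
            scaler=scaler,
            train_config=train_cfg,
            n_train_real=n_real,
            n_train_synthetic=len(train_bags) - n_real,
        )


class MILResults:
    """Fitted MIL classifier: parameters, loss curve, prediction, attention."""

    def __init__(
        self,
        model: MILModel,
        params: dict[str, np.ndarray],
        loss_curve: np.ndarray,
        scaler: FeatureScaler,
        train_config: TrainConfig,
        n_train_real: int,
        n_train_synthetic: int,
    ):
        self.model = model
        self.config = model.config
        self.max_bag_size = model.max_bag_size
        self.schema_hash = model.schema.hash()
        self.params = params
        self.loss_curve = np.asarray(loss_curve)
        self.scaler = scaler
        self.train_config = train_config
        self.n_train_real = n_train_real
        self.n_train_synthetic = n_train_synthetic

    # ---- prediction -----------------------------------------------------

    def _prepare(self, bags: list[Bag]):
        n_feat = bags[0].matrix.shape[1]
        if n_feat != self.config.input_dim:
            raise DataError(
                f"bags have {n_feat} features, model expects {self.config.input_dim}"
            )
        scaled = self.scaler.transform_bags(bags)
        # fresh but fixed stream: repeated predictions are identical
        rng = np.random.default_rng(np.random.PCG64(self.train_config.seed + 2**20))
        return pad_bags(scaled, self.max_bag_size, rng, on_oversize="error")

    def predict_proba(self, bags: list[Bag]) -> np.ndarray:
        probs, _, _ = predict_padded(self._prepare(bags), self.params, self.config)
        return probs

    def predict(self, bags: list[Bag], threshold: float = 0.5) -> np.ndarray:
        """Hard labels; a probability exactly at the threshold is positive."""
        _, labels, _ = predict_padded(
            self._prepare(bags), self.params, self.config, threshold=threshold
        )
        return labels

    def attention(self, bags: list[Bag]) -> list[MILPrediction]:
        """Per-bag predictions with slot- and nodule-level attention weights."""
        _, _, preds = predict_padded(self._prepare(bags), self.params, self.config)
        return preds

    # ---- reporting ------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "MIL classifier results",
            "=" * 58,
            f"pooling:            {cfg.pooling}" + (" (gated)" if cfg.gated else ""),
            f"architecture:       {cfg.input_dim} -> {cfg.hidden_dims[0]} -> "
            f"{cfg.hidden_dims[1]} (attention dim {cfg.attention_dim})",
            f"dropout:            {cfg.dropout}",
            f"max bag size:       {self.max_bag_size}",
            f"training bags:      {self.n_train_real} real + "
            f"{self.n_train_synthetic} synthetic",
            f"optimizer:          SGD, batch {self.train_config.batch_size}, "
            f"lr {self.train_config.learning_rate:g}, "
            f"{self.train_config.epochs} epochs, seed {self.train_config.seed}",
        ]
        if self.loss_curve.size:
            lines += [
                f"initial loss:       {self.loss_curve[0]:.4f}",
                f"final loss:         {self.loss_curve[-1]:.4f}",
            ]
        lines.append("=" * 58)
        return "\n".join(lines)

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Single-file JSON checkpoint: config + parameters + scaler + schema hash."""
        payload = {
            "format": "milrad-checkpoint-v1",
            "model_config": self.config.to_dict(),
            "train_config": self.train_config.to_dict(),
            "max_bag_size": self.max_bag_size,
            "schema_hash": self.schema_hash,
            "scaler": self.scaler.to_dict(),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "loss_curve": self.loss_curve.tolist(),
            "n_train_real": self.n_train_real,
            "n_train_synthetic": self.n_train_synthetic,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike, schema: FeatureSchema | None = None) -> "MILResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "milrad-checkpoint-v1":
            raise ValueError(f"{path}: not a milrad checkpoint")
        schema = schema or default_schema()
        if payload["schema_hash"] != schema.hash():
            raise DataError(
                "checkpoint schema hash does not match the provided feature schema"
            )
        cfg = MILModelConfig.from_dict(payload["model_config"])
        scaler = FeatureScaler.from_dict(payload["scaler"])
        # reconstruct a shell model; the training bags are not persisted
        shell = MILModel.__new__(MILModel)
        shell.bags = []
        shell.schema = schema
        shell.config = cfg
        shell.max_bag_size = payload["max_bag_size"]
        res = cls(
            model=shell,
            params={k: np.asarray(v, float) for k, v in payload["params"].items()},
            loss_curve=np.asarray(payload["loss_curve"], float),
            scaler=scaler,
            train_config=TrainConfig(**payload["train_config"]),
            n_train_real=payload["n_train_real"],
            n_train_synthetic=payload["n_train_synthetic"],
        )
        return res
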