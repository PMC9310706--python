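"""The attention-based deep MIL network and its pooling variants.

Each padded bag (max_bag_size x n_features) is passed instance-wise through a
transformation network of fully connected layers with ReLU activations and
dropout.  The instance embeddings h_k are pooled into a single bag embedding

    attention:  z = sum_k a_k h_k,   a = softmax_k( w^T tanh(V h_k) )
    mean:       z = mean_k h_k                       (naive MIL baseline)
    max:        z = elementwise max_k h_k            (MI-Net-style baseline)

and a final fully connected layer with a sigmoid gives the bag probability.
The attention weights a_k are softmax-normalized and serve as per-nodule
importance scores.  A gated attention variant (tanh * sigmoid gates) is
available but off by default.

The forward and backward passes are written directly in numpy; gradients are
derived analytically and validated against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bagging import PaddedBag

__all__ = [
    "MILModelConfig",
    "MILPrediction",
    "init_params",
    "forward",
    "backward",
    "aggregate_instance_attention",
    "loss_and_grads",
]

POOLINGS = ("attention", "mean", "max")


@dataclass
class MILModelConfig:
    """Architecture of the MIL classifier.

    Defaults: 103-dim input, transformation layers 103->64->32, attention
    dimension 16, dropout 0.5 (active during training only).
    """

    input_dim: int = 103
    hidden_dims: tuple[int, int] = (64, 32)
    attention_dim: int = 16
    dropout: float = 0.5
    pooling: str = "attention"
    gated: bool = False

    def __post_init__(self) -> None:
        if self.pooling not in POOLINGS:
            raise ValueError(f"pooling must be one of {POOLINGS}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.input_dim < 1 or any(h < 1 for h in self.hidden_dims) or self.attention_dim < 1:
            raise ValueError("all layer dimensions must be positive")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden_dims": list(self.hidden_dims),
            "attention_dim": self.attention_dim,
            "dropout": self.dropout,
            "pooling": self.pooling,
            "gated": self.gated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MILModelConfig":
        d = dict(d)
        d["hidden_dims"] = tuple(d["hidden_dims"])
        return cls(**d)


@dataclass
class MILPrediction:
    """Bag-level probability plus normalized per-slot attention weights."""

    subject_id: str
    bag_prob: float
    slot_weights: np.ndarray  # (n_slots,), non-negative, sums to 1
    slot_source: np.ndarray
    nodule_ids: list[str]

    def instance_attention(self) -> dict[str, float]:
        """Per-nodule attention: each nodule's slots' weights summed."""
        return aggregate_instance_attention(
            self.slot_weights, self.slot_source, self.nodule_ids
        )


def aggregate_instance_attention(
    slot_weights: np.ndarray, slot_source: np.ndarray, nodule_ids: list[str]
) -> dict[str, float]:
    """Sum padded-slot weights back onto their source nodules (sums to 1)."""
    if len(slot_weights) != len(slot_source):
        raise ValueError("slot_weights and slot_source length mismatch")
    per_instance = np.bincount(
        np.asarray(slot_source), weights=slot_weights, minlength=len(nodule_ids)
    )
    return {nid: float(a) for nid, a in zip(nodule_ids, per_instance)}


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def init_params(config: MILModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases; seed-controlled via ``rng``."""
    d, (h1, h2), a = config.input_dim, config.hidden_dims, config.attention_dim
    params = {
        "W1": _glorot(rng, h1, d),
        "b1": np.zeros(h1),
        "W2": _glorot(rng, h2, h1),
        "b2": np.zeros(h2),
        "u": _glorot(rng, 1, h2)[0],
        "c": np.zeros(1),
    }
    if config.pooling == "attention":
        params["V"] = _glorot(rng, a, h2)
        params["w"] = _glorot(rng, 1, a)[0]
        if config.gated:
            params["U"] = _glorot(rng, a, h2)
            params["g"] = _glorot(rng, 1, a)[0]
    return params


def forward(
    padded: PaddedBag,
    params: dict[str, np.ndarray],
    config: MILModelConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    _cache: dict | None = None,
) -> MILPrediction:
    """Run the network on one padded bag.

    Dropout is active only when ``train_mode`` is true (inverted dropout, so
    evaluation needs no rescaling).  When ``_cache`` is supplied the
    intermediate activations needed for backprop are stored in it.
    """
    X = padded.matrix
    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"bag feature dimension {X.shape[1]} does not match model input_dim "
            f"{config.input_dim}"
        )
    keep = 1.0 - config.dropout
    use_dropout = train_mode and config.dropout > 0.0
    if use_dropout and rng is None:
        raise ValueError("train_mode with dropout requires an rng")

    A1 = params["W1"] @ X.T + params["b1"][:, None]  # (h1, K)
    H1 = np.maximum(A1, 0.0)
    if use_dropout:
        M1 = (rng.random(H1.shape) < keep) / keep
        H1 = H1 * M1
    A2 = params["W2"] @ H1 + params["b2"][:, None]  # (h2, K)
    H2 = np.maximum(A2, 0.0)
    if use_dropout:
        M2 = (rng.random(H2.shape) < keep) / keep
        H2 = H2 * M2

    K = X.shape[0]
    if config.pooling == "attention":
        T = np.tanh(params["V"] @ H2)  # (a, K)
        if config.gated:
            G = 1.0 / (1.0 + np.exp(-(params["U"] @ H2)))
            scores = (params["w"] @ T) * (params["g"] @ G)
        else:
            scores = params["w"] @ T  # (K,)
        e = np.exp(scores - scores.max())
        a_w = e / e.sum()
        z = H2 @ a_w
    elif config.pooling == "mean":
        a_w = np.full(K, 1.0 / K)
        z = H2.mean(axis=1)
    else:  # max
        argmax = H2.argmax(axis=1)
        z = H2[np.arange(H2.shape[0]), argmax]
        # report each slot's share of embedding dimensions it wins
        a_w = np.bincount(argmax, minlength=K) / H2.shape[0]

    logit = float(params["u"] @ z + params["c"][0])
    prob = 1.0 / (1.0 + np.exp(-logit))

    if _cache is not None:
        _cache.update(
            X=X, A1=A1, H1=H1, A2=A2, H2=H2, a_w=a_w, z=z, prob=prob,
            M1=M1 if use_dropout else None, M2=M2 if use_dropout else None,
        )
        if config.pooling == "attention":
            _cache["T"] = T
            if config.gated:
                _cache["G"] = G
        elif config.pooling == "max":
            _cache["argmax"] = argmax

    return MILPrediction(
        subject_id=padded.subject_id,
        bag_prob=prob,
        slot_weights=a_w,
        slot_source=padded.slot_source,
        nodule_ids=padded.nodule_ids,
    )


def backward(
    cache: dict,
    label: int,
    params: dict[str, np.ndarray],
    config: MILModelConfig,
) -> dict[str, np.ndarray]:
    """Analytic gradients of the Bernoulli NLL for one bag.

    Loss: L = -[y log p + (1-y) log(1-p)], so dL/dlogit = p - y.
    """
    X, H1, H2 = cache["X"], cache["H1"], cache["H2"]
    a_w, z, prob = cache["a_w"], cache["z"], cache["prob"]
    dlogit = prob - label

    grads = {
        "u": dlogit * z,
        "c": np.array([dlogit]),
    }
    dz = dlogit * params["u"]  # (h2,)

    if config.pooling == "attention":
        T = cache["T"]
        dH2 = np.outer(dz, a_w)
        da = H2.T @ dz  # (K,)
        ds = a_w * (da - a_w @ da)  # softmax backward -> score grads
        if config.gated:
            G = cache["G"]
            wT = params["w"] @ T
            gG = params["g"] @ G
            grads["w"] = T @ (ds * gG)
            grads["g"] = G @ (ds * wT)
            dT = np.outer(params["w"], ds * gG)
            dG = np.outer(params["g"], ds * wT)
            dpreT = dT * (1.0 - T**2)
            dpreG = dG * G * (1.0 - G)
            grads["V"] = dpreT @ H2.T
            grads["U"] = dpreG @ H2.T
            dH2 = dH2 + params["V"].T @ dpreT + params["U"].T @ dpreG
        else:
            grads["w"] = T @ ds
            dpreT = np.outer(params["w"], ds) * (1.0 - T**2)
            grads["V"] = dpreT @ H2.T
            dH2 = dH2 + params["V"].T @ dpreT
    elif config.pooling == "mean":
        K = H2.shape[1]
        dH2 = np.outer(dz, np.full(K, 1.0 / K))
    else:  # max
        dH2 = np.zeros_like(H2)
        dH2[np.arange(H2.shape[0]), cache["argmax"]] = dz

    if cache["M2"] is not None:
        dH2 = dH2 * cache["M2"]
    dA2 = dH2 * (cache["A2"] > 0)
    grads["W2"] = dA2 @ H1.T
    grads["b2"] = dA2.sum(axis=1)
    dH1 = params["W2"].T @ dA2
    if cache["M1"] is not None:
        dH1 = dH1 * cache["M1"]
    dA1 = dH1 * (cache["A1"] > 0)
    grads["W1"] = dA1 @ X
    grads["b1"] = dA1.sum(axis=1)
    return grads


def loss_and_grads(
    padded: PaddedBag,
    label: int,
    params: dict[str, np.ndarray],
    config: MILModelConfig,
    train_mode: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Bernoulli NLL and its gradients for a single bag."""
    cache: dict = {}
    forward(padded, params, config, train_mode=train_mode, rng=rng, _cache=cache)
    p = np.clip(cache["prob"], 1e-12, 1.0 - 1e-12)
    loss = -(label * np.log(p) + (1 - label) * np.log(1.0 - p))
    grads = backward(cache, label, params, config)
    return float(loss), grads
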