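"""Synthetic feature-bag generator.

Emulates the statistical structure the classifier assumes so the whole
pipeline can be exercised and validated without the study imaging data:
background nodules are multivariate Gaussian noise; signal (malignant-like)
nodules are shifted by a configurable effect size on a subset of features;
a subject is positive iff its bag contains at least one signal nodule (the
standard MIL assumption, which holds exactly by construction).  Ground-truth
instance flags are emitted in the ``instance_signal`` column and are never
used by training.

``simulate_lidc_like`` reproduces the study-data marginals: 110 subjects
(82 positive / 28 negative), 310 nodules in total, bag sizes 1..12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import Bag, InstanceFeatures

__all__ = ["SimConfig", "simulate_dataset", "simulate_lidc_like"]


@dataclass
class SimConfig:
    """Generator settings.

    ``effect_size`` is the mean shift of signal nodules on the signal
    features, in units of the background standard deviation.
    ``witness_rate`` is the expected fraction of signal nodules per positive
    bag; at least one signal nodule per positive bag is always enforced.
    Bag sizes follow a geometric distribution truncated to
    ``bag_size_range`` (success probability ``bag_size_geom_p``), which
    matches the strongly right-skewed nodule counts of screening data
    (mean around 2.8 nodules per subject).  Setting ``block_size`` > 1 adds
    equicorrelated feature blocks (correlation ``block_rho``) to mimic
    radiomics collinearity; the default is independent features.
    """

    n_subjects: int = 110
    positive_fraction: float = 0.75
    n_features: int = 103
    signal_features: int = 10
    effect_size: float = 3.0
    witness_rate: float = 0.5
    noise_sd: float = 1.0
    bag_size_range: tuple[int, int] = (1, 12)
    bag_size_geom_p: float = 0.33
    block_size: int = 1
    block_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")
        if not (0.0 < self.witness_rate <= 1.0):
            raise ValueError("witness_rate must be in (0, 1]")
        if self.signal_features < 1 or self.signal_features > self.n_features:
            raise ValueError("signal_features must be in 1..n_features")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid bag_size_range")


def _truncated_geometric(rng: np.random.Generator, p: float, lo: int, hi: int, size: int) -> np.ndarray:
    support = np.arange(lo, hi + 1)
    pmf = (1.0 - p) ** (support - lo) * p
    pmf = pmf / pmf.sum()
    return rng.choice(support, size=size, p=pmf)


def _noise(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    x = rng.standard_normal((n, cfg.n_features))
    if cfg.block_size > 1 and cfg.block_rho > 0:
        # equicorrelated blocks: shared factor per block of consecutive features
        n_blocks = int(np.ceil(cfg.n_features / cfg.block_size))
        shared = rng.standard_normal((n, n_blocks))
        shared_full = np.repeat(shared, cfg.block_size, axis=1)[:, : cfg.n_features]
        x = np.sqrt(cfg.block_rho) * shared_full + np.sqrt(1.0 - cfg.block_rho) * x
    return x * cfg.noise_sd


def _make_bags(
    sizes: np.ndarray,
    labels: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    signal_idx: np.ndarray,
) -> list[Bag]:
    bags: list[Bag] = []
    for s, (size, label) in enumerate(zip(sizes, labels)):
        sid = f"SUBJ-{s:04d}"
        size = int(size)
        x = _noise(rng, size, cfg)
        flags = np.zeros(size, dtype=int)
        if label == 1:
            n_signal = max(1, int(rng.binomial(size, cfg.witness_rate)))
            which = rng.choice(size, size=n_signal, replace=False)
            flags[which] = 1
            x[np.ix_(which, signal_idx)] += cfg.effect_size * cfg.noise_sd
        instances = [
            InstanceFeatures(
                subject_id=sid,
                nodule_id=f"N{j:02d}",
                values=x[j],
                signal=int(flags[j]),
            )
            for j in range(size)
        ]
        bags.append(Bag(subject_id=sid, instances=instances, label=int(label)))
    return bags


def simulate_dataset(cfg: SimConfig) -> tuple[list[Bag], dict]:
    """Generate bags under ``cfg``; labels are Bernoulli(positive_fraction).

    Returns the bags (instances carry ground-truth ``signal`` flags) and an
    info dict with the signal feature indices used.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bag_size_range
    sizes = _truncated_geometric(rng, cfg.bag_size_geom_p, lo, hi, cfg.n_subjects)
    labels = (rng.random(cfg.n_subjects) < cfg.positive_fraction).astype(int)
    signal_idx = np.sort(rng.choice(cfg.n_features, size=cfg.signal_features, replace=False))
    bags = _make_bags(sizes, labels, cfg, rng, signal_idx)
    return bags, {"signal_feature_indices": signal_idx.tolist()}


def simulate_lidc_like(seed: int = 0, cfg: SimConfig | None = None) -> list[Bag]:
    """Fixed-marginal dataset matching the study data.

    Exactly 110 subjects, 82 positive / 28 negative, 310 nodules in total,
    with a maximum bag size of 12 (at least one bag at the maximum).  Bag
    sizes start from the truncated geometric draw and are then adjusted by
    largest-remainder-style increments/decrements until the total is 310.
    """
    cfg = cfg or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    n, n_pos, total = 110, 82, 310
    lo, hi = 1, 12

    sizes = _truncated_geometric(rng, cfg.bag_size_geom_p, lo, hi, n).astype(int)
    sizes[int(rng.integers(n))] = hi  # guarantee one bag at the maximum
    guard = int(np.argmax(sizes == hi))
    while sizes.sum() != total:
        if sizes.sum() > total:
            candidates = np.flatnonzero((sizes > lo) & (np.arange(n) != guard))
            sizes[rng.choice(candidates)] -= 1
        else:
            candidates = np.flatnonzero(sizes < hi)
            sizes[rng.choice(candidates)] += 1

    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    signal_idx = np.sort(rng.choice(cfg.n_features, size=cfg.signal_features, replace=False))
    return _make_bags(sizes, labels, cfg, rng, signal_idx)
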