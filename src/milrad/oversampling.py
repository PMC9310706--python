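"""Class-imbalance correction by simulating synthetic bags.

Every nodule in a subject without lung cancer is, by definition, a
non-cancerous nodule, so new negative subjects can be simulated by drawing
nodules from the pooled instances of all real negative training subjects.
Synthetic bags are built from the training split only and never enter a test
split.  The mirror-image positive-bag augmentation (padding real positive
bags with pooled instances) is provided but disabled by default, matching a
study population where positives are the majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import Bag, DataError, InstanceFeatures

__all__ = [
    "NegativeInstancePool",
    "OversampleConfig",
    "build_negative_pool",
    "build_instance_pool",
    "simulate_negative_bags",
    "simulate_positive_bags",
]


@dataclass
class NegativeInstancePool:
    """Aggregated instances from all negative training bags."""

    instances: list[InstanceFeatures]

    def __len__(self) -> int:
        return len(self.instances)


@dataclass
class OversampleConfig:
    """How many synthetic bags to add to a training split.

    ``size_sampler`` is either ``"empirical"`` (bag sizes drawn uniformly from
    the multiset of real negative-bag sizes in the training split) or
    ``"uniform"`` (uniform on 1..max_bag_size).
    """

    n_synthetic_negative: int = 60
    n_synthetic_positive: int = 0
    size_sampler: str = "empirical"

    def __post_init__(self) -> None:
        if self.n_synthetic_negative < 0 or self.n_synthetic_positive < 0:
            raise ValueError("synthetic bag counts must be non-negative")
        if self.size_sampler not in ("empirical", "uniform"):
            raise ValueError("size_sampler must be 'empirical' or 'uniform'")


def build_negative_pool(train_bags: list[Bag]) -> NegativeInstancePool:
    """Concatenate the instances of every label-0 training bag."""
    negatives = [bag for bag in train_bags if bag.label == 0]
    if not negatives:
        raise DataError(
            "training split has no negative bags; disable oversampling "
            "(n_synthetic_negative=0) or provide negative subjects"
        )
    instances = [inst for bag in negatives for inst in bag.instances]
    return NegativeInstancePool(instances=instances)


def build_instance_pool(train_bags: list[Bag]) -> list[InstanceFeatures]:
    """Pool of instances from bags of BOTH classes (positive-bag augmentation)."""
    return [inst for bag in train_bags for inst in bag.instances]


def _draw_sizes(
    n: int,
    cfg: OversampleConfig,
    negative_sizes: list[int],
    max_bag_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if cfg.size_sampler == "empirical":
        if not negative_sizes:
            raise DataError("empirical size sampler needs at least one negative bag")
        return rng.choice(np.asarray(negative_sizes), size=n, replace=True)
    return rng.integers(1, max_bag_size + 1, size=n)


def simulate_negative_bags(
    pool: NegativeInstancePool,
    n_synthetic: int,
    max_bag_size: int,
    rng: np.random.Generator,
    cfg: OversampleConfig | None = None,
    negative_sizes: list[int] | None = None,
    id_prefix: str = "SYN-NEG",
) -> list[Bag]:
    """Simulate ``n_synthetic`` label-0 bags by resampling the negative pool.

    Within a bag, instances are sampled without replacement (a synthetic
    subject never contains the same physical nodule twice); across bags,
    sampling is with replacement.
    """
    if n_synthetic == 0:
        return []
    if len(pool) == 0:
        raise DataError("negative instance pool is empty")
    cfg = cfg or OversampleConfig()
    if negative_sizes is None:
        negative_sizes = []
    sizes = _draw_sizes(n_synthetic, cfg, negative_sizes, max_bag_size, rng)
    bags: list[Bag] = []
    for i, size in enumerate(sizes):
        size = int(min(size, max_bag_size))
        if size > len(pool):
            raise DataError(
                f"requested synthetic bag size {size} exceeds pool size {len(pool)}"
            )
        chosen = rng.choice(len(pool), size=size, replace=False)
        sid = f"{id_prefix}-{i:04d}"
        instances = [
            InstanceFeatures(
                subject_id=sid,
                nodule_id=f"{pool.instances[j].subject_id}/{pool.instances[j].nodule_id}",
                values=pool.instances[j].values,
                signal=pool.instances[j].signal,
            )
            for j in chosen
        ]
        bags.append(Bag(subject_id=sid, instances=instances, label=0, synthetic=True))
    return bags


def simulate_positive_bags(
    positive_bags: list[Bag],
    pool: list[InstanceFeatures],
    n_synthetic: int,
    max_bag_size: int,
    rng: np.random.Generator,
    id_prefix: str = "SYN-POS",
) -> list[Bag]:
    """Simulate positive bags by adding pooled instances to real positive bags.

    Each synthetic bag is a uniformly chosen real positive bag plus k >= 1
    pooled instances, k uniform on 1..(max_bag_size - bag size).  Positive
    bags already at full size are never augmented; if every positive bag is
    full the result is empty.
    """
    if n_synthetic == 0:
        return []
    if not positive_bags:
        raise DataError("no positive bags to augment")
    eligible = [bag for bag in positive_bags if len(bag) < max_bag_size]
    if not eligible:
        return []
    bags: list[Bag] = []
    for i in range(n_synthetic):
        base = eligible[rng.integers(len(eligible))]
        k = int(rng.integers(1, max_bag_size - len(base) + 1))
        chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        sid = f"{id_prefix}-{i:04d}"
        instances = [
            InstanceFeatures(sid, inst.nodule_id, inst.values, inst.signal)
            for inst in base.instances
        ] + [
            InstanceFeatures(
                sid,
                f"{pool[j].subject_id}/{pool[j].nodule_id}",
                pool[j].values,
                pool[j].signal,
            )
            for j in chosen
        ]
        bags.append(Bag(subject_id=sid, instances=instances, label=1, synthetic=True))
    return bags
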