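"""Pad bags to a fixed size by balanced duplication of their own nodules.

The network takes a fixed (max_bag_size x n_features) matrix per subject.
Smaller bags are filled by duplicating their nodules as evenly as possible:
with n nodules and target size M, q = M // n and r = M % n, exactly r
nodules (chosen uniformly at random) appear q+1 times and the remaining
n - r appear q times.  For a 5-nodule bag padded to 12 this gives three
nodules twice and two nodules three times.  Padding is applied identically
at training and at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import Bag, DataError

__all__ = ["PaddedBag", "pad_bag", "pad_bags", "infer_max_bag_size"]


@dataclass
class PaddedBag:
    """Fixed-size bag matrix plus the map from padded slots back to nodules."""

    subject_id: str
    matrix: np.ndarray  # (max_bag_size, n_features)
    slot_source: np.ndarray  # (max_bag_size,) source instance index per slot
    label: int
    nodule_ids: list[str]
    synthetic: bool = False

    @property
    def n_slots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_instances(self) -> int:
        return len(self.nodule_ids)

    def copy_counts(self) -> np.ndarray:
        """Number of padded slots occupied by each source instance."""
        return np.bincount(self.slot_source, minlength=self.n_instances)


def infer_max_bag_size(bags: list[Bag]) -> int:
    """Largest bag size in the data (12 for the LIDC-derived study data)."""
    if not bags:
        raise DataError("cannot infer max bag size from an empty bag list")
    return max(len(bag) for bag in bags)


def pad_bag(bag: Bag, max_bag_size: int, rng: np.random.Generator) -> PaddedBag:
    """Pad one bag to ``max_bag_size`` rows by balanced duplication.

    The only randomness is which ``r`` nodules receive the extra copy and the
    order of slots; a bag already at full size passes through unchanged.
    """
    n = len(bag)
    if max_bag_size < 1:
        raise ValueError("max_bag_size must be positive")
    if n > max_bag_size:
        raise DataError(
            f"bag {bag.subject_id!r} has {n} instances, more than max_bag_size="
            f"{max_bag_size}; re-pad with a larger max_bag_size"
        )
    x = bag.matrix
    if n == max_bag_size:
        slot_source = np.arange(n)
        matrix = x.copy()
    else:
        q, r = divmod(max_bag_size, n)
        counts = np.full(n, q, dtype=int)
        if r:
            extra = rng.choice(n, size=r, replace=False)
            counts[extra] += 1
        slot_source = np.repeat(np.arange(n), counts)
        rng.shuffle(slot_source)
        matrix = x[slot_source]
    return PaddedBag(
        subject_id=bag.subject_id,
        matrix=matrix,
        slot_source=slot_source,
        label=bag.label,
        nodule_ids=[inst.nodule_id for inst in bag.instances],
        synthetic=bag.synthetic,
    )


def pad_bags(
    bags: list[Bag],
    max_bag_size: int | None = None,
    rng: np.random.Generator | None = None,
    on_oversize: str = "error",
) -> list[PaddedBag]:
    """Pad every bag to a common size.

    ``max_bag_size`` defaults to the largest bag present.  ``on_oversize``
    controls bags larger than the requested size: ``"error"`` rejects them,
    ``"grow"`` raises the padding target to fit.
    """
    if max_bag_size is None:
        max_bag_size = infer_max_bag_size(bags)
    elif on_oversize == "grow":
        max_bag_size = max(max_bag_size, infer_max_bag_size(bags))
    elif on_oversize != "error":
        raise ValueError("on_oversize must be 'error' or 'grow'")
    rng = rng if rng is not None else np.random.default_rng()
    return [pad_bag(bag, max_bag_size, rng) for bag in bags]
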