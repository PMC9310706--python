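"""Core data containers: feature schema, per-nodule instances, and subject bags.

A *bag* is one subject (patient): the set of segmented lung nodules found in
their CT examination, each represented by a fixed-length vector of radiomics
features.  Labels attach to bags only (1 = lung cancer, 0 = not lung cancer);
individual nodules are unlabeled, which is the defining property of multiple
instance learning.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureSchema",
    "InstanceFeatures",
    "Bag",
    "default_schema",
    "DataError",
    "SchemaError",
]


class SchemaError(ValueError):
    """The feature table does not match the expected column schema."""


class DataError(ValueError):
    """The feature table content is internally inconsistent."""


# Radiomics feature-class sizes for the supported 103-feature signature:
# morphology (shape), intensity histogram (first-order), texture (Haralick).
FEATURE_CLASS_COUNTS = {"shape": 13, "firstorder": 17, "texture": 73}


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names plus their split into radiomics classes.

    Parameters
    ----------
    feature_names
        Ordered, unique identifiers, one per feature column.
    class_counts
        Mapping from feature class to count; must sum to ``len(feature_names)``.
    """

    feature_names: tuple[str, ...]
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(FEATURE_CLASS_COUNTS)
    )

    def __post_init__(self) -> None:
        names = tuple(self.feature_names)
        object.__setattr__(self, "feature_names", names)
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        total = sum(self.class_counts.values())
        if total != len(names):
            raise SchemaError(
                f"class counts sum to {total} but schema has {len(names)} features"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def hash(self) -> str:
        """Stable digest of the ordered feature names (checkpoint guard)."""
        h = hashlib.sha256("\n".join(self.feature_names).encode("utf-8"))
        return h.hexdigest()[:16]


def default_schema() -> FeatureSchema:
    """The canonical 103-feature schema (13 shape + 17 first-order + 73 texture).

    Feature columns are named ``f_001`` .. ``f_103`` in class order.
    """
    names = tuple(f"f_{i:03d}" for i in range(1, 104))
    return FeatureSchema(feature_names=names)


@dataclass
class InstanceFeatures:
    """One nodule: its ids and radiomics feature vector.

    ``signal`` carries the ground-truth instance flag when known (synthetic
    data); it is never used by training.
    """

    subject_id: str
    nodule_id: str
    values: np.ndarray
    signal: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("instance feature vector must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError(
                f"non-finite feature value for subject {self.subject_id!r} "
                f"nodule {self.nodule_id!r}"
            )


@dataclass
class Bag:
    """One subject: ordered nodule instances plus the subject-level label."""

    subject_id: str
    instances: list[InstanceFeatures]
    label: int
    synthetic: bool = False

    def __post_init__(self) -> None:
        if len(self.instances) < 1:
            raise DataError(f"bag {self.subject_id!r} has no instances")
        if self.label not in (0, 1):
            raise DataError(f"bag {self.subject_id!r} label must be 0 or 1")
        if not self.synthetic:
            for inst in self.instances:
                if inst.subject_id != self.subject_id:
                    raise DataError(
                        f"instance subject_id {inst.subject_id!r} does not match "
                        f"bag {self.subject_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def matrix(self) -> np.ndarray:
        """(n_instances, n_features) stacked feature vectors."""
        return np.stack([inst.values for inst in self.instances])
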