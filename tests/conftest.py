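import numpy as np
import pytest

from milrad import Bag, FeatureSchema, InstanceFeatures


def make_schema(d: int) -> FeatureSchema:
    """Small d-feature schema for fast unit tests."""
    return FeatureSchema(
        feature_names=tuple(f"f_{i:03d}" for i in range(1, d + 1)),
        class_counts={"shape": d},
    )


def make_bag(
    subject_id: str,
    n_instances: int,
    n_features: int = 6,
    label: int = 0,
    rng: np.random.Generator | None = None,
) -> Bag:
    rng = rng if rng is not None else np.random.default_rng(abs(hash(subject_id)) % 2**31)
    return Bag(
        subject_id=subject_id,
        instances=[
            InstanceFeatures(
                subject_id=subject_id,
                nodule_id=f"N{j:02d}",
                values=rng.standard_normal(n_features),
            )
            for j in range(n_instances)
        ],
        label=label,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
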