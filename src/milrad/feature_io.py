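"""Read/write per-nodule feature tables and leakage-free feature scaling.

The canonical input is a CSV/TSV table with one row per nodule:

    subject_id, nodule_id, label, [instance_signal], f_001 .. f_103

Rows sharing a ``subject_id`` form one bag; the subject-level ``label`` must
be identical across a subject's rows.  ``instance_signal`` is an optional
ground-truth column emitted by the synthetic generator and ignored by
training.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import Bag, DataError, FeatureSchema, InstanceFeatures, SchemaError, default_schema

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "bags_to_dataframe",
    "dataframe_to_bags",
    "FeatureScaler",
    "standardize_features",
]

ID_COLUMNS = ("subject_id", "nodule_id", "label")
SIGNAL_COLUMN = "instance_signal"


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def dataframe_to_bags(df: pd.DataFrame, schema: FeatureSchema | None = None) -> list[Bag]:
    """Group a per-nodule table into one :class:`Bag` per subject.

    Subject order follows first appearance; row order within a subject is
    preserved.  Raises :class:`SchemaError` for missing columns and
    :class:`DataError` for conflicting labels or non-numeric features.
    """
    schema = schema or default_schema()
    missing = [c for c in (*ID_COLUMNS, *schema.feature_names) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    feat = df.loc[:, list(schema.feature_names)]
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy().any(axis=1) | ~np.isfinite(numeric.to_numpy()).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(f"non-numeric or non-finite feature value at table row {row}")
    values = numeric.to_numpy(dtype=float)

    has_signal = SIGNAL_COLUMN in df.columns
    bags: list[Bag] = []
    subject_ids = df["subject_id"].astype(str)
    for sid in subject_ids.drop_duplicates():
        idx = np.flatnonzero((subject_ids == sid).to_numpy())
        labels = set(df["label"].iloc[idx].astype(int))
        if len(labels) != 1:
            raise DataError(f"subject {sid!r} has conflicting labels {sorted(labels)}")
        instances = [
            InstanceFeatures(
                subject_id=sid,
                nodule_id=str(df["nodule_id"].iloc[i]),
                values=values[i],
                signal=int(df[SIGNAL_COLUMN].iloc[i]) if has_signal else None,
            )
            for i in idx
        ]
        bags.append(Bag(subject_id=sid, instances=instances, label=labels.pop()))
    return bags


def read_feature_table(path: str | os.PathLike, schema: FeatureSchema | None = None) -> list[Bag]:
    """Read a CSV/TSV feature table into bags (one per subject)."""
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    return dataframe_to_bags(df, schema)


def bags_to_dataframe(bags: list[Bag], schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Flatten bags back to the per-nodule table (inverse of grouping)."""
    schema = schema or default_schema()
    records = []
    any_signal = any(inst.signal is not None for bag in bags for inst in bag.instances)
    for bag in bags:
        for inst in bag.instances:
            rec = {
                "subject_id": bag.subject_id,
                "nodule_id": inst.nodule_id,
                "label": bag.label,
            }
            if any_signal:
                rec[SIGNAL_COLUMN] = 0 if inst.signal is None else int(inst.signal)
            rec.update(zip(schema.feature_names, inst.values))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def write_feature_table(
    bags: list[Bag], path: str | os.PathLike, schema: FeatureSchema | None = None
) -> None:
    """Write bags as a CSV/TSV table; values round-trip at full precision."""
    df = bags_to_dataframe(bags, schema)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


@dataclass
class FeatureScaler:
    """Per-feature z-scoring with parameters fit on training instances only.

    Features with zero training variance are mapped to 0 everywhere (their
    standardized value is defined as 0 rather than dividing by zero).
    """

    mean: np.ndarray
    scale: np.ndarray  # 1/sd, with 0 where sd == 0

    @classmethod
    def fit(cls, bags: list[Bag]) -> "FeatureScaler":
        if not bags:
            raise DataError("cannot fit scaler on an empty training set")
        x = np.concatenate([bag.matrix for bag in bags], axis=0)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        scale = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 0.0)
        return cls(mean=mean, scale=scale)

    def transform_bags(self, bags: list[Bag]) -> list[Bag]:
        out = []
        for bag in bags:
            instances = [
                InstanceFeatures(
                    subject_id=inst.subject_id,
                    nodule_id=inst.nodule_id,
                    values=(inst.values - self.mean) * self.scale,
                    signal=inst.signal,
                )
                for inst in bag.instances
            ]
            out.append(
                Bag(
                    subject_id=bag.subject_id,
                    instances=instances,
                    label=bag.label,
                    synthetic=bag.synthetic,
                )
            )
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean=np.asarray(d["mean"], float), scale=np.asarray(d["scale"], float))


def standardize_features(
    train_bags: list[Bag], apply_bags: list[Bag] | None = None
) -> tuple[list[Bag], list[Bag], FeatureScaler]:
    """Z-score features using mean/sd from *training* instances only.

    Returns the transformed training bags, the transformed ``apply_bags``
    (e.g. a test fold), and the fitted scaler for later reuse.
    """
    scaler = FeatureScaler.fit(train_bags)
    train_t = scaler.transform_bags(train_bags)
    apply_t = scaler.transform_bags(apply_bags) if apply_bags else []
    return train_t, apply_t, scaler
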