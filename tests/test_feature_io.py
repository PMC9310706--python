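"""Feature-table IO, schema validation and leakage-free standardization."""

import numpy as np
import pandas as pd
import pytest

from milrad import (
    DataError,
    FeatureSchema,
    SchemaError,
    bags_to_dataframe,
    dataframe_to_bags,
    default_schema,
    read_feature_table,
    simulate_lidc_like,
    standardize_features,
    write_feature_table,
)
from milrad.feature_io import FeatureScaler

from conftest import make_bag, make_schema


def small_table(d=3):
    schema = make_schema(d)
    df = pd.DataFrame(
        {
            "subject_id": ["a", "a", "a", "b"],
            "nodule_id": ["n0", "n1", "n2", "n0"],
            "label": [1, 1, 1, 0],
            **{name: np.arange(4) + i for i, name in enumerate(schema.feature_names)},
        }
    )
    return df, schema


class TestSchema:
    def test_default_schema_is_the_103_feature_signature(self):
        schema = default_schema()
        assert schema.n_features == 103
        assert schema.class_counts == {"shape": 13, "firstorder": 17, "texture": 73}
        assert sum(schema.class_counts.values()) == 103
        assert len(set(schema.feature_names)) == 103

    def test_inconsistent_class_counts_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema(feature_names=("a", "b"), class_counts={"shape": 3})

    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema(feature_names=("a", "a"), class_counts={"shape": 2})


class TestReadFeatureTable:
    def test_rows_grouped_into_bags_by_subject(self):
        df, schema = small_table()
        bags = dataframe_to_bags(df, schema)
        assert [b.subject_id for b in bags] == ["a", "b"]
        assert [len(b) for b in bags] == [3, 1]
        assert [b.label for b in bags] == [1, 0]
        # row order within subject preserved
        assert [i.nodule_id for i in bags[0].instances] == ["n0", "n1", "n2"]

    def test_conflicting_labels_within_subject_rejected(self):
        df, schema = small_table()
        df.loc[1, "label"] = 0
        with pytest.raises(DataError, match="conflicting labels"):
            dataframe_to_bags(df, schema)

    def test_missing_column_named_in_error(self):
        df, schema = small_table()
        with pytest.raises(SchemaError, match="f_002"):
            dataframe_to_bags(df.drop(columns=["f_002"]), schema)

    def test_non_numeric_feature_reports_row(self):
        df, schema = small_table()
        df["f_001"] = df["f_001"].astype(object)
        df.loc[2, "f_001"] = "oops"
        with pytest.raises(DataError, match="row 2"):
            dataframe_to_bags(df, schema)

    def test_lidc_like_table_has_study_marginals(self, tmp_path):
        bags = simulate_lidc_like(3)
        path = tmp_path / "synth.csv"
        write_feature_table(bags, path)
        loaded = read_feature_table(path)
        assert len(loaded) == 110
        assert sum(len(b) for b in loaded) == 310

    def test_write_read_round_trip_full_precision(self, tmp_path):
        bags = simulate_lidc_like(7)[:20]
        path = tmp_path / "rt.csv"
        write_feature_table(bags, path)
        loaded = read_feature_table(path)
        for orig, back in zip(bags, loaded):
            assert orig.subject_id == back.subject_id
            assert orig.label == back.label
            np.testing.assert_array_equal(orig.matrix, back.matrix)
            assert [i.signal for i in orig.instances] == [
                i.signal for i in back.instances
            ]

    def test_dataframe_round_trip(self):
        df, schema = small_table()
        bags = dataframe_to_bags(df, schema)
        back = bags_to_dataframe(bags, schema)
        pd.testing.assert_frame_equal(
            back.astype(df.dtypes), df, check_dtype=False
        )


class TestStandardize:
    def test_zero_variance_feature_maps_to_zero(self, rng):
        bags = [make_bag(f"s{i}", 3, n_features=4, rng=rng) for i in range(3)]
        for b in bags:
            for inst in b.instances:
                inst.values[2] = 7.5  # constant feature
        out, _, scaler = standardize_features(bags)
        stacked = np.concatenate([b.matrix for b in out])
        assert np.all(stacked[:, 2] == 0.0)
        assert scaler.scale[2] == 0.0

    def test_single_training_instance_maps_to_zero(self):
        bag = make_bag("solo", 1, n_features=5)
        out, _, _ = standardize_features([bag])
        np.testing.assert_array_equal(out[0].matrix, 0.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(DataError):
            FeatureScaler.fit([])

    def test_recovers_generator_moments(self, rng):
        mu, sd = 3.0, 2.0
        bags = []
        for i in range(200):
            b = make_bag(f"s{i}", 5, n_features=3, rng=rng)
            for inst in b.instances:
                inst.values = mu + sd * rng.standard_normal(3)
            bags.append(b)
        scaler = FeatureScaler.fit(bags)  # 1000 instances
        assert np.allclose(scaler.mean, mu, rtol=0.05)
        assert np.allclose(1.0 / scaler.scale, sd, rtol=0.05)

    def test_standardization_idempotent(self, rng):
        bags = [make_bag(f"s{i}", 4, n_features=6, rng=rng) for i in range(10)]
        once, _, _ = standardize_features(bags)
        twice, _, _ = standardize_features(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-10)

    def test_scaler_fit_on_train_only(self, rng):
        train = [make_bag(f"t{i}", 3, n_features=2, rng=rng) for i in range(5)]
        test = [make_bag("x", 3, n_features=2, rng=rng)]
        for inst in test[0].instances:
            inst.values = inst.values + 100.0  # shifted test data
        _, test_t, scaler = standardize_features(train, test)
        # test transform uses train moments, so the shift survives
        assert test_t[0].matrix.mean() > 10.0
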