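import numpy as np
import pytest

from emrfuse.data_model import DatasetSchema, SchemaError
from emrfuse.preprocessing import (Preprocessor, Vocab,
                                   discretize_and_onehot_static,
                                   impute_temporal_tabular, merge_and_pad,
                                   segment_windows, tokenize)

from conftest import make_record


class TestTokenize:
    def test_whitespace_split(self):
        assert tokenize("chest pain onset") == ["chest", "pain", "onset"]

    def test_empty_string(self):
        assert tokenize("") == []

    def test_pretokenized_passes_through(self):
        assert tokenize(["chest", "pain"]) == ["chest", "pain"]

    def test_custom_tokenizer_injected(self):
        assert tokenize("a-b", tokenizer=lambda s: s.split("-")) == ["a", "b"]


class TestImputation:
    def test_linear_interpolation_midpoint(self, tiny_schema):
        rec = make_record(los=3, obs=[(1, "hr", 2.0), (3, "hr", 4.0)])
        values, mask = impute_temporal_tabular(rec, tiny_schema)
        assert values[1, 0] == pytest.approx(3.0)  # day 2 midpoint
        assert mask[:, 0].tolist() == [1.0, 0.0, 1.0]

    def test_edge_fill_before_first_observation(self, tiny_schema):
        # 5-day record, first observation on day 3: days 1-2 take its value
        rec = make_record(los=5, obs=[(3, "hr", 7.0), (5, "hr", 9.0)])
        values, _ = impute_temporal_tabular(rec, tiny_schema)
        assert values[:3, 0].tolist() == [7.0, 7.0, 7.0]
        assert values[4, 0] == pytest.approx(9.0)

    def test_never_observed_feature_uses_training_median(self, tiny_schema):
        # toy cohort medians: lactate observed at 1.0, 2.0, 10.0 -> median 2.0
        train = [make_record(f"t{i}", los=2, obs=[(1, "lactate", v)])
                 for i, v in enumerate([1.0, 2.0, 10.0])]
        pre = Preprocessor(tiny_schema).fit(train)
        assert pre.medians["lactate"] == pytest.approx(2.0)
        rec = make_record(los=4, obs=[(1, "hr", 80.0)])
        values, mask = impute_temporal_tabular(rec, tiny_schema, pre.medians)
        assert np.all(values[:, 1] == 2.0)
        assert np.all(mask[:, 1] == 0.0)

    def test_same_day_duplicate_first_wins(self, tiny_schema):
        rec = make_record(los=2, obs=[(1, "hr", 5.0), (1, "hr", 99.0)])
        values, _ = impute_temporal_tabular(rec, tiny_schema)
        assert values[0, 0] == pytest.approx(5.0)


class TestMergeAndPad:
    def test_long_stay_merges_post_horizon_observation(self, tiny_schema):
        # 35-day stay, hr observed on days 1 and 35: day-30 value is day 35's
        rec = make_record(los=35, obs=[(1, "hr", 60.0), (35, "hr", 120.0)])
        values, mask = impute_temporal_tabular(rec, tiny_schema)
        out_v, out_m, notes = merge_and_pad(values, mask, {}, tiny_schema)
        assert out_v.shape == (30, 2)
        assert out_v[29, 0] == pytest.approx(120.0)
        assert out_m[29, 0] == 1.0

    def test_exact_horizon_stay_is_identity(self, tiny_schema):
        rec = make_record(los=30, obs=[(1, "hr", 60.0), (30, "hr", 65.0)])
        values, mask = impute_temporal_tabular(rec, tiny_schema)
        out_v, out_m, _ = merge_and_pad(values, mask, {}, tiny_schema)
        np.testing.assert_array_equal(out_v, values)
        np.testing.assert_array_equal(out_m, mask)

    def test_short_stay_forward_fills_with_zero_mask(self, tiny_schema):
        rec = make_record(los=7, obs=[(2, "hr", 70.0), (7, "hr", 75.0)])
        values, mask = impute_temporal_tabular(rec, tiny_schema)
        out_v, out_m, notes = merge_and_pad(values, mask, {1: ["a"]}, tiny_schema)
        for day in range(7, 30):
            np.testing.assert_array_equal(out_v[day], out_v[6])
            assert np.all(out_m[day] == 0.0)
        assert all(notes[d] == [] for d in range(7, 30))

    def test_post_horizon_notes_concatenated_in_day_order(self, tiny_schema):
        notes_by_day = {29: ["x"], 30: ["a", "b"], 32: ["c"], 35: ["d"]}
        rec = make_record(los=35, obs=[(1, "hr", 60.0)])
        values, mask = impute_temporal_tabular(rec, tiny_schema)
        _, _, notes = merge_and_pad(values, mask, notes_by_day, tiny_schema)
        assert notes[28] == ["x"]
        assert notes[29] == ["a", "b", "c", "d"]

    def test_merged_note_respects_token_budget(self, tiny_schema):
        notes_by_day = {30: ["a"] * 40, 31: ["b"] * 40}
        rec = make_record(los=31)
        values, mask = impute_temporal_tabular(rec, tiny_schema)
        _, _, notes = merge_and_pad(values, mask, notes_by_day, tiny_schema,
                                    note_budget=50)
        assert len(notes[29]) == 50
        assert notes[29][:40] == ["a"] * 40


class TestSegmentation:
    def test_default_geometry_gives_ten_windows(self, tiny_schema):
        values = np.arange(60, dtype=float).reshape(30, 2)
        mask = np.ones_like(values)
        daily = [[f"d{i}"] for i in range(30)]
        win_v, win_m, win_notes = segment_windows(values, mask, daily, tiny_schema)
        assert win_v.shape == (10, 3, 2)
        assert len(win_notes) == 10

    def test_windows_partition_the_grid_exactly(self, tiny_schema):
        values = np.random.default_rng(0).normal(size=(30, 2))
        daily = [[f"d{i}"] for i in range(30)]
        win_v, _, win_notes = segment_windows(values, np.ones_like(values),
                                              daily, tiny_schema)
        np.testing.assert_array_equal(win_v.reshape(30, 2), values)
        assert sum(win_notes, []) == sum(daily, [])  # day order preserved

    def test_degenerate_single_window(self):
        schema = DatasetSchema(temporal_features=["hr"], horizon_days=30,
                               window_days=30)
        values = np.arange(30, dtype=float).reshape(30, 1)
        win_v, _, _ = segment_windows(values, np.ones_like(values),
                                      [[] for _ in range(30)], schema)
        assert win_v.shape == (1, 30, 1)
        np.testing.assert_array_equal(win_v[0], values)

    def test_indivisible_window_length_rejected(self):
        with pytest.raises(SchemaError):
            DatasetSchema(temporal_features=["hr"], horizon_days=30, window_days=4)


class TestStaticOneHot:
    def test_above_range_maps_to_high(self, tiny_schema):
        vec = discretize_and_onehot_static({"temperature": 38.5, "sex": "male"},
                                           tiny_schema)
        assert vec[:3].tolist() == [0.0, 0.0, 1.0]  # low, normal, high

    def test_boundary_value_counts_as_normal(self, tiny_schema):
        vec = discretize_and_onehot_static({"temperature": 37.2, "sex": "male"},
                                           tiny_schema)
        assert vec[:3].tolist() == [0.0, 1.0, 0.0]

    def test_categorical_group_length_and_single_one(self, tiny_schema):
        vec = discretize_and_onehot_static({"temperature": 36.5, "sex": "female"},
                                           tiny_schema)
        group = vec[3:]
        assert len(group) == 3  # two categories + UNK
        assert group.sum() == 1.0 and group[1] == 1.0

    def test_unseen_category_hits_unk_slot(self, tiny_schema):
        vec = discretize_and_onehot_static({"temperature": 36.5, "sex": "other"},
                                           tiny_schema)
        assert vec[3:].tolist() == [0.0, 0.0, 1.0]

    def test_every_group_sums_to_one_on_cohort(self, windowed_cohort, cohort_schema):
        sizes = [3] * len(cohort_schema.static_continuous) + [
            len(f.categories) + 1 for f in cohort_schema.static_categorical]
        for w in windowed_cohort[:50]:
            off = 0
            for size in sizes:
                assert w.static_onehot[off:off + size].sum() == 1.0
                off += size


class TestVocab:
    def test_encode_maps_unknown_to_unk(self):
        vocab = Vocab.fit([["a", "a", "b"]], max_size=10)
        ids = vocab.encode(["a", "b", "zzz"])
        assert ids[2] == 1  # UNK
        assert ids[0] != ids[2]

    def test_max_size_caps_vocabulary(self):
        docs = [[f"w{i}" for i in range(100)]]
        assert len(Vocab.fit(docs, max_size=20)) == 20


class TestCohortInvariants:
    def test_mask_conservation(self, cohort, cohort_schema, windowed_cohort):
        """Mask entries equal the distinct observed (capped-day, feature) pairs."""
        H = cohort_schema.horizon_days
        for rec, win in zip(cohort[:60], windowed_cohort[:60]):
            expected = len({(min(o.day, H), o.feature) for o in rec.temporal_tabular})
            assert int(win.subseq_tabular_mask.sum()) == expected

    def test_windowed_shapes(self, windowed_cohort, cohort_schema):
        n, W = cohort_schema.n_windows, cohort_schema.window_days
        F = len(cohort_schema.temporal_features)
        for w in windowed_cohort:
            assert w.subseq_tabular.shape == (n, W, F)
            assert w.subseq_tabular_mask.shape == (n, W, F)
            assert len(w.subseq_notes) == n
            assert set(np.unique(w.subseq_tabular_mask)) <= {0.0, 1.0}
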