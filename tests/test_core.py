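import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathsea.core import (
    OmicsDataSet,
    SampleDesign,
    combine_datasets,
    condition_means,
    normalize_profiles,
    quantile_normalize,
    read_design,
    read_feature_table,
    write_feature_table,
)

from .conftest import make_design


def _write_small_ms(tmp_path, design: SampleDesign):
    feat = tmp_path / "features.csv"
    pd.DataFrame(
        {
            "feature_id": ["f1", "f2", "f3"],
            "mz": [181.07, 203.05, 150.0],
            "rt": [5.0, 5.02, 7.5],
            **{
                s: np.arange(3, dtype=float) + 10 * (j + 1)
                for j, s in enumerate(design.sample_ids)
            },
        }
    ).to_csv(feat, index=False)
    des = tmp_path / "design.csv"
    design.write_csv(des)
    return feat, des


class TestReadWrite:
    def test_round_trip_is_value_identical(self, tmp_path):
        design = make_design(n_conditions=3, units_per_condition=2)
        feat, des = _write_small_ms(tmp_path, design)
        ds = read_feature_table(feat, des, "metabolomics", "positive")
        assert ds.n_features == 3 and ds.n_samples == 6
        assert ds.design.conditions == ("c1", "c2", "c3")
        out = tmp_path / "copy.csv"
        write_feature_table(ds, out)
        ds2 = read_feature_table(out, des, "metabolomics", "positive")
        np.testing.assert_array_equal(ds.intensities, ds2.intensities)
        np.testing.assert_array_equal(ds.mz, ds2.mz)
        assert ds.feature_ids == ds2.feature_ids

    def test_unknown_sample_named_in_error(self, tmp_path):
        design = make_design()
        feat, des = _write_small_ms(tmp_path, design)
        df = pd.read_csv(feat).rename(columns={design.sample_ids[0]: "mystery"})
        df.to_csv(feat, index=False)
        with pytest.raises(ValueError, match="mystery"):
            read_feature_table(feat, des, "metabolomics", "positive")

    def test_duplicate_feature_id_rejected(self, tmp_path):
        design = make_design()
        feat, des = _write_small_ms(tmp_path, design)
        df = pd.read_csv(feat)
        df.loc[1, "feature_id"] = "f1"
        df.to_csv(feat, index=False)
        with pytest.raises(ValueError, match="duplicate feature id"):
            read_feature_table(feat, des, "metabolomics", "positive")

    def test_transcript_table_with_mz_warns_and_ignores(self, tmp_path):
        design = make_design()
        feat, des = _write_small_ms(tmp_path, design)
        with pytest.warns(UserWarning, match="mz"):
            ds = read_feature_table(feat, des, "transcriptomics")
        assert ds.mz is None and ds.rt is None

    def test_missing_and_negative_intensities_rejected(self, tmp_path):
        design = make_design()
        feat, des = _write_small_ms(tmp_path, design)
        df = pd.read_csv(feat)
        df.loc[0, design.sample_ids[0]] = np.nan
        df.to_csv(feat, index=False)
        with pytest.raises(ValueError, match="f1"):
            read_feature_table(feat, des, "metabolomics", "positive")
        df.loc[0, design.sample_ids[0]] = -3.0
        df.to_csv(feat, index=False)
        with pytest.raises(ValueError, match="negative"):
            read_feature_table(feat, des, "metabolomics", "positive")

    def test_unit_in_two_conditions_rejected(self, tmp_path):
        des = tmp_path / "bad_design.csv"
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "condition": ["a", "b"],
                "biounit": ["u1", "u1"],
                "dataset": ["d", "d"],
            }
        ).to_csv(des, index=False)
        with pytest.raises(ValueError, match="two conditions"):
            read_design(des)


class TestQuantileNormalize:
    def test_two_column_example(self):
        m = np.array([[6.0, 1.0], [2.0, 5.0], [4.0, 3.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [5.5, 1.5, 3.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 5.5, 3.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 7.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_single_column_unchanged(self):
        m = np.array([[4.0], [1.0], [9.0]])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_ties_receive_mean_of_spanned_rank_means(self):
        # rank means are [2, 2.5, 3.5]; the tied 1s span ranks 1-2 -> 2.25
        m = np.array([[1.0, 3.0], [1.0, 4.0], [2.0, 5.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [2.25, 2.25, 3.5])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.empty((0, 3)))

    @given(
        arrays(
            np.float64,
            (7, 4),
            elements=st.floats(0, 1e6, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_column_sums_equal(self, m):
        out = quantile_normalize(m)
        sums = out.sum(axis=0)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9, atol=1e-6)


class TestProfiles:
    def test_condition_means_example(self):
        design = make_design(n_conditions=2, units_per_condition=2)
        ds = OmicsDataSet(
            label="d",
            kind="other",
            feature_ids=("f1",),
            intensities=np.array([[1.0, 3.0, 5.0, 7.0]]),
            design=design,
        )
        means, conds = condition_means(ds)
        np.testing.assert_allclose(means, [[2.0, 6.0]])
        assert conds == ("c1", "c2")

    def test_condition_means_match_brute_force(self, rng):
        design = make_design(n_conditions=6, units_per_condition=3, tech_reps=2)
        x = rng.uniform(0, 100, (20, len(design.sample_ids)))
        ds = OmicsDataSet(
            label="d",
            kind="other",
            feature_ids=tuple(f"f{i}" for i in range(20)),
            intensities=x,
            design=design,
        )
        means, conds = condition_means(ds)
        for fi in range(20):
            for ci, c in enumerate(conds):
                vals = [
                    x[fi, j]
                    for j, s in enumerate(design.sample_ids)
                    if design.condition_of[s] == c
                ]
                assert means[fi, ci] == pytest.approx(np.mean(vals))

    def test_normalize_three_four_five(self):
        out, excluded = normalize_profiles(np.array([[3.0, 4.0], [0.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.6, 0.8]])
        assert excluded == [1]

    @given(
        arrays(
            np.float64,
            (5, 6),
            elements=st.floats(0, 1e4, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_normalized_rows_have_unit_norm(self, m):
        out, _ = normalize_profiles(m)
        if out.size:
            np.testing.assert_allclose(
                np.linalg.norm(out, axis=1), 1.0, atol=1e-12
            )


class TestCombine:
    def _ds(self, label, n, design, kind="other", rng=None):
        rng = rng or np.random.default_rng(abs(hash(label)) % 2**31)
        return OmicsDataSet(
            label=label,
            kind=kind,
            feature_ids=tuple(f"{label}_f{i}" for i in range(n)),
            intensities=rng.uniform(1, 10, (n, len(design.sample_ids))),
            design=design,
        )

    def test_five_filtered_sets_concatenate_to_total(self):
        # the five filtered table sizes of a published cross-omics study
        design = make_design(n_conditions=6, units_per_condition=3)
        sizes = [316, 313, 161, 234, 2809]
        combined = combine_datasets(
            [self._ds(f"d{i}", n, design) for i, n in enumerate(sizes)]
        )
        assert combined.n_rows == 3833
        assert list(combined.rows.groupby("source").size()[
            [f"d{i}" for i in range(5)]
        ]) == sizes

    def test_single_input_identity(self):
        design = make_design()
        ds = self._ds("only", 4, design)
        combined = combine_datasets([ds])
        assert combined.n_rows == 4
        assert set(combined.rows["source"]) == {"only"}
        np.testing.assert_allclose(combined.profiles, condition_means(ds)[0])

    def test_condition_mismatch_reported(self):
        d1 = make_design(n_conditions=2)
        d2 = make_design(n_conditions=3)
        with pytest.raises(ValueError, match="condition lists differ"):
            combine_datasets([self._ds("a", 3, d1), self._ds("b", 3, d2)])

    def test_provenance_preserved_per_row(self):
        design = make_design()
        a = self._ds("a", 3, design, kind="other")
        b = self._ds("b", 2, design, kind="transcriptomics")
        combined = combine_datasets([a, b])
        assert list(combined.rows["kind"]) == ["other"] * 3 + ["transcriptomics"] * 2
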