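"""Phenotype table parsing, discretization, encoding and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mass_select import (
    PhenotypeMatrix,
    discretize_growth,
    drop_attributes,
    drop_incomplete_samples,
    drop_samples,
    encode_for_mass,
    read_phenotype_table,
    spearman_filter,
    write_phenotype_table,
)


class TestReadWrite:
    def test_numeric_csv(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("id,a,b\ns1,0,1\ns2,1,0\ns3,1,1\n")
        m = read_phenotype_table(f)
        assert m.n_samples == 3 and m.n_attributes == 2
        assert m.values[0, 1] == 1.0

    def test_declared_missing_symbol(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("id,a,b\ns1,?,1\ns2,1,0\n")
        m = read_phenotype_table(f, missing_symbols=("?",))
        assert np.isnan(m.values[0, 0])

    def test_undeclared_symbol_names_cell(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("id,a,b\ns1,x,1\ns2,1,0\n")
        with pytest.raises(ValueError, match="s1"):
            read_phenotype_table(f)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("id,a,b\ns1,0,1\ns1,1,0\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            read_phenotype_table(f)

    def test_categorical_with_level_map(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("id\tc1\ns1\t+\ns2\t-\n")
        m = read_phenotype_table(
            f,
            level_set=["negative", "positive"],
            level_map={"+": "positive", "-": "negative"},
        )
        assert m.values[0, 0] == "positive"

    def test_roundtrip(self, tmp_path, binary_matrix):
        f = tmp_path / "out.tsv"
        write_phenotype_table(binary_matrix, f)
        back = read_phenotype_table(f)
        np.testing.assert_array_equal(back.values, binary_matrix.values)
        assert back.sample_ids == binary_matrix.sample_ids


class TestDiscretize:
    @pytest.mark.parametrize(
        "col,threshold,expected",
        [
            ([0.0, 0.8, 0.0], 0.0, [0.0, 1.0, 0.0]),
            ([0.0, 0.0, 0.0], 0.0, [0.0, 0.0, 0.0]),
            ([0.2, 0.6, 0.4], 0.5, [0.0, 1.0, 0.0]),
        ],
    )
    def test_threshold_rule(self, col, threshold, expected):
        m = PhenotypeMatrix([f"s{i}" for i in range(3)], ["a"], np.array(col).reshape(-1, 1))
        out = discretize_growth(m, threshold=threshold)
        np.testing.assert_array_equal(out.values[:, 0], expected)

    def test_categorical_rejected(self, categorical_matrix):
        with pytest.raises(TypeError):
            discretize_growth(categorical_matrix)


class TestEncode:
    def test_binary_column(self):
        m = PhenotypeMatrix(["s1", "s2", "s3"], ["a"], np.array([[0.0], [1.0], [1.0]]))
        enc = encode_for_mass(m)
        np.testing.assert_array_equal(enc.values[:, 0], [-1.0, 1.0, 1.0])
        assert enc.groups == {"a": [0]}

    def test_three_level_doubles_features(self):
        # 37 three-level attributes with the negative level dropped give
        # 2 dummies each: 74 features in 37 groups
        rng = np.random.default_rng(0)
        levels = ["negative", "weak", "positive"]
        vals = np.array(rng.choice(levels, size=(5, 37)), dtype=object)
        m = PhenotypeMatrix(
            [f"s{i}" for i in range(5)], [f"c{j}" for j in range(37)], vals, level_set=levels
        )
        enc = encode_for_mass(m, drop_level="negative")
        assert enc.n_features == 74
        assert len(enc.groups) == 37
        assert all(len(g) == 2 for g in enc.groups.values())

    def test_dropped_level_sample_all_minus_one(self):
        levels = ["negative", "weak", "positive"]
        vals = np.array([["negative"], ["positive"]], dtype=object)
        m = PhenotypeMatrix(["s1", "s2"], ["c"], vals, level_set=levels)
        enc = encode_for_mass(m, drop_level="negative")
        np.testing.assert_array_equal(enc.values[0], [-1.0, -1.0])

    def test_missing_values_instruct_dropping(self, categorical_matrix):
        vals = categorical_matrix.values.copy()
        vals[0, 0] = None
        m = PhenotypeMatrix(
            categorical_matrix.sample_ids,
            categorical_matrix.attribute_ids,
            vals,
            level_set=categorical_matrix.level_set,
        )
        with pytest.raises(ValueError, match="drop_incomplete_samples"):
            encode_for_mass(m, drop_level="negative")

    def test_categorical_requires_drop_level(self, categorical_matrix):
        with pytest.raises(ValueError, match="drop_level"):
            encode_for_mass(categorical_matrix)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_roundtrip_and_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 12)), int(rng.integers(2, 6))
        levels = ["negative", "weak", "positive"]
        vals = np.array(rng.choice(levels, size=(n, m)), dtype=object)
        mat = PhenotypeMatrix(
            [f"s{i}" for i in range(n)], [f"c{j}" for j in range(m)], vals, level_set=levels
        )
        enc = encode_for_mass(mat, drop_level="negative")
        assert np.isin(enc.values, (-1.0, 1.0)).all()
        assert sorted(i for g in enc.groups.values() for i in g) == list(
            range(enc.n_features)
        )
        back = enc.decode()
        np.testing.assert_array_equal(back.values, mat.values)


class TestSpearmanFilter:
    def test_identical_columns_dropped(self):
        vals = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 0.0]])
        m = PhenotypeMatrix([f"s{i}" for i in range(4)], ["a", "b"], vals)
        out, audit = spearman_filter(m, threshold=0.74)
        assert out.attribute_ids == ["a"]
        assert audit[0][:2] == ("b", "a")

    def test_anticorrelated_dropped(self):
        vals = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0], [0.0, 2.0]])
        m = PhenotypeMatrix([f"s{i}" for i in range(4)], ["a", "b"], vals)
        out, audit = spearman_filter(m, threshold=0.74)
        assert out.attribute_ids == ["a"]
        assert audit[0][2] == pytest.approx(-1.0)

    def test_independent_columns_survive(self):
        # oracle: rank correlation computed directly from rank transforms
        rng = np.random.default_rng(42)
        a, b = rng.random(200), rng.random(200)
        ranks = lambda x: np.argsort(np.argsort(x)).astype(float)
        rho = np.corrcoef(ranks(a), ranks(b))[0, 1]
        assert abs(rho) <= 0.74
        m = PhenotypeMatrix(
            [f"s{i}" for i in range(200)], ["a", "b"], np.column_stack([a, b])
        )
        out, audit = spearman_filter(m, threshold=0.74)
        assert out.attribute_ids == ["a", "b"] and audit == []

    def test_constant_column_survives(self, caplog):
        vals = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        m = PhenotypeMatrix(["s1", "s2", "s3"], ["const", "b"], vals)
        out, _ = spearman_filter(m)
        assert out.attribute_ids == ["const", "b"]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_no_retained_pair_exceeds_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 30, 6
        base = rng.integers(0, 3, size=(n, m)).astype(float)
        base[:, -1] = base[:, 0]  # guarantee at least one redundant pair
        mat = PhenotypeMatrix(
            [f"s{i}" for i in range(n)], [f"c{j}" for j in range(m)], base
        )
        out, _ = spearman_filter(mat, threshold=0.74)
        from scipy.stats import spearmanr

        codes = out.codes()
        for j in range(out.n_attributes):
            for k in range(j + 1, out.n_attributes):
                if np.ptp(codes[:, j]) == 0 or np.ptp(codes[:, k]) == 0:
                    continue
                rho = spearmanr(codes[:, j], codes[:, k]).statistic
                assert abs(rho) <= 0.74 + 1e-12


class TestDropOps:
    def test_drop_incomplete_samples(self):
        vals = np.array([[1.0, 2.0], [np.nan, 1.0], [0.0, 1.0]])
        m = PhenotypeMatrix(["s1", "s2", "s3"], ["a", "b"], vals)
        out = drop_incomplete_samples(m)
        assert out.sample_ids == ["s1", "s3"]

    def test_no_missing_is_identity(self, binary_matrix):
        out = drop_incomplete_samples(binary_matrix)
        assert out.sample_ids == binary_matrix.sample_ids

    def test_all_missing_errors(self):
        m = PhenotypeMatrix(["s1"], ["a"], np.array([[np.nan]]))
        with pytest.raises(ValueError):
            drop_incomplete_samples(m)

    def test_drop_one_of_38_attributes(self):
        rng = np.random.default_rng(0)
        m = PhenotypeMatrix(
            ["s1", "s2"],
            [f"c{j}" for j in range(38)],
            rng.integers(0, 2, size=(2, 38)).astype(float),
        )
        out = drop_attributes(m, ["c0"])
        assert out.n_attributes == 37

    def test_drop_empty_identity(self, binary_matrix):
        assert drop_samples(binary_matrix, []).sample_ids == binary_matrix.sample_ids
        assert drop_attributes(binary_matrix, []).attribute_ids == ["a", "b"]

    def test_drop_unknown_errors(self, binary_matrix):
        with pytest.raises(KeyError):
            drop_attributes(binary_matrix, ["zzz"])
        with pytest.raises(KeyError):
            drop_samples(binary_matrix, ["zzz"])
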