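import numpy as np
import pytest

from eqtlmeta.datamodel import (
    ExpressionMatrix,
    GenotypeVector,
    TissueSampleMap,
    build_sharing_matrix,
    read_expression_table,
    read_genotype_table,
    read_sample_map,
    row_individual_indicator,
    stack_design,
    standardize_expression,
    write_sample_map,
)


class TestSharingMatrix:
    def test_three_tissue_design_is_nine_by_nine(self, three_tissue_maps):
        K = build_sharing_matrix(three_tissue_maps)
        assert K.shape == (9, 9)
        assert np.array_equal(K, K.T)
        assert np.array_equal(np.diag(K), np.ones(9))

    def test_disjoint_individuals_give_identity(self):
        maps = [
            TissueSampleMap("a", ("x1", "x2", "x3")),
            TissueSampleMap("b", ("y1", "y2", "y3")),
        ]
        assert np.array_equal(build_sharing_matrix(maps), np.eye(6, dtype=int))

    def test_fully_shared_rows_sum_to_tissue_count(self):
        ids = tuple(f"S{i}" for i in range(4))
        maps = [TissueSampleMap(f"t{j}", ids) for j in range(3)]
        K = build_sharing_matrix(maps)
        assert K.shape == (12, 12)
        # each row pairs with the same individual once per tissue
        assert np.array_equal(K.sum(axis=1), np.full(12, 3))
        off_diag = K - np.eye(12, dtype=K.dtype)
        assert np.array_equal(off_diag.sum(axis=1), np.full(12, 2))

    def test_equals_indicator_gram_matrix(self, three_tissue_maps):
        K = build_sharing_matrix(three_tissue_maps)
        M = row_individual_indicator(three_tissue_maps)
        assert np.array_equal(K, (M @ M.T > 0).astype(K.dtype))

    def test_empty_tissue_rejected(self):
        with pytest.raises(ValueError, match="tissueX"):
            TissueSampleMap("tissueX", ())

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TissueSampleMap("t", ("a", "a"))


class TestStackDesign:
    def test_nine_row_three_intercept_layout(
        self, three_tissue_expression, three_tissue_genotype, three_tissue_maps
    ):
        d = stack_design(
            three_tissue_expression, three_tissue_genotype, three_tissue_maps, "g1"
        )
        assert d.y.shape == (9,)
        assert d.intercept_block.shape == (9, 3)
        assert d.snp_block.shape == (9, 3)
        # intercept columns are disjoint indicator blocks covering all rows
        assert np.array_equal(d.intercept_block.sum(axis=1), np.ones(9))
        assert np.array_equal(d.intercept_block.sum(axis=0), np.full(3, 3.0))
        # dosages sit exactly where the intercepts do
        assert np.array_equal(d.snp_block != 0, (d.intercept_block != 0) & (d.snp_block != 0))
        expected_first_block = three_tissue_genotype.values_for(("S1", "S2", "S3"))
        assert np.array_equal(d.snp_block[:3, 0], expected_first_block)
        assert d.tissue_index[:3] == ("T1",) * 3
        assert d.sample_index[3:6] == ("S1", "S2", "S4")

    def test_single_tissue_reduces_to_simple_regression_design(self):
        maps = [TissueSampleMap("only", ("a", "b", "c", "d"))]
        expr = [
            ExpressionMatrix("only", ("p",), ("a", "b", "c", "d"),
                             np.arange(4.0)[None, :])
        ]
        geno = GenotypeVector("s", {"a": 0, "b": 1, "c": 2, "d": 1})
        d = stack_design(expr, geno, maps, "p")
        assert np.array_equal(d.intercept_block, np.ones((4, 1)))
        assert np.array_equal(d.snp_block[:, 0], [0, 1, 2, 1])
        assert np.array_equal(d.sharing_matrix, np.eye(4, dtype=int))

    def test_one_shared_individual_gives_two_off_diagonal_ones(self):
        maps = [
            TissueSampleMap("t1", ("shared", "u1", "u2")),
            TissueSampleMap("t2", ("shared", "v1", "v2")),
        ]
        K = build_sharing_matrix(maps)
        assert K.sum() == 6 + 2  # diagonal plus the one shared pair, twice

    def test_missing_probe_and_genotype_errors(
        self, three_tissue_expression, three_tissue_genotype, three_tissue_maps
    ):
        with pytest.raises(KeyError, match="nope"):
            stack_design(
                three_tissue_expression, three_tissue_genotype,
                three_tissue_maps, "nope",
            )
        incomplete = GenotypeVector("rs1", {"S1": 0.0, "S2": 1.0})
        with pytest.raises(KeyError, match="genotype"):
            stack_design(
                three_tissue_expression, incomplete, three_tissue_maps, "g1"
            )


class TestStandardize:
    def test_rows_become_zero_mean_unit_variance(self):
        em = ExpressionMatrix(
            "t", ("p1", "p2"), ("a", "b", "c"),
            np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 8.0]]),
        )
        out = standardize_expression(em)
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)
        assert np.allclose(out.values[0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        em = ExpressionMatrix("t", ("p",), tuple("abcde"), rng.normal(size=(1, 5)))
        once = standardize_expression(em)
        twice = standardize_expression(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_constant_probe_listed_in_error(self):
        em = ExpressionMatrix(
            "liver", ("flat", "ok"), ("a", "b", "c"),
            np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]),
        )
        with pytest.raises(ValueError, match="flat"):
            standardize_expression(em)


class TestTsvRoundTrip:
    def test_fixture_round_trips_and_restacks(
        self, tmp_path, three_tissue_expression, three_tissue_maps,
        three_tissue_genotype,
    ):
        import pandas as pd

        gpath = tmp_path / "geno.tsv"
        pd.DataFrame(
            [three_tissue_genotype.dosage],
            index=pd.Index([three_tissue_genotype.snp_id], name="snp_id"),
        ).to_csv(gpath, sep="\t")
        mpath = tmp_path / "map.tsv"
        write_sample_map(three_tissue_maps, mpath)
        epaths = {}
        for em in three_tissue_expression:
            p = tmp_path / f"expr_{em.tissue_id}.tsv"
            pd.DataFrame(
                em.values, index=pd.Index(em.probe_ids, name="probe_id"),
                columns=em.sample_ids,
            ).to_csv(p, sep="\t")
            epaths[em.tissue_id] = p

        maps2 = read_sample_map(mpath)
        assert [m.tissue_id for m in maps2] == ["T1", "T2", "T3"]
        assert maps2[1].sample_ids == ("S1", "S2", "S4")
        geno_df = read_genotype_table(gpath)
        from eqtlmeta.datamodel import genotype_vector

        geno2 = genotype_vector(geno_df, "rs1")
        expr2 = [read_expression_table(epaths[m.tissue_id], m.tissue_id) for m in maps2]
        d1 = stack_design(
            three_tissue_expression, three_tissue_genotype, three_tissue_maps, "g1"
        )
        d2 = stack_design(expr2, geno2, maps2, "g1")
        assert np.allclose(d1.y, d2.y)
        assert np.array_equal(d1.sharing_matrix, d2.sharing_matrix)
        assert np.allclose(d1.snp_block, d2.snp_block)
        assert d1.sample_index == d2.sample_index
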