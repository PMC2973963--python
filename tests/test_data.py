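import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiensemble.data import (
    ENVIRONMENT,
    SNP,
    FactorValueSpec,
    GenotypeMatrix,
    ParseError,
    PhenotypeLabels,
    allelic_chi2,
    discretize_age,
    filter_by_association,
    filter_by_missingness,
    impute_mode,
    read_genotype_table,
    write_genotype_table,
)

from conftest import make_matrix


class TestReadWrite:
    def test_tsv_roundtrip_parses_codes_and_labels(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("snpA\tsnpB\tclass\n0\t1\t1\n2\t0\t0\n1\tNA\t1\n")
        gm, labels = read_genotype_table(path)
        assert gm.factor_ids == ["snpA", "snpB"]
        assert gm.n_samples == 3
        assert labels.labels.tolist() == [1, 0, 1]
        assert gm.missing_mask[2, 1] and gm.missing_mask.sum() == 1
        out = tmp_path / "out.tsv"
        write_genotype_table(gm, labels, out)
        gm2, labels2 = read_genotype_table(out)
        assert gm2.factor_ids == gm.factor_ids
        assert (gm2.missing_mask == gm.missing_mask).all()
        assert (gm2.values[~gm2.missing_mask] == gm.values[~gm.missing_mask]).all()
        assert (labels2.labels == labels.labels).all()

    def test_invalid_genotype_code_names_row_and_column(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("snpA\tsnpB\tclass\n0\t1\t1\n5\t0\t0\n")
        with pytest.raises(ParseError, match=r"row 1.*snpA"):
            read_genotype_table(path)

    def test_single_class_file_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("snpA\tclass\n0\t1\n1\t1\n")
        with pytest.raises(ValueError, match="single-class"):
            read_genotype_table(path)

    def test_plink_raw_dialect(self, tmp_path):
        path = tmp_path / "d.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C\n"
            "f1 i1 0 0 1 2 0 2\n"
            "f2 i2 0 0 2 1 1 NA\n"
        )
        gm, labels = read_genotype_table(path, dialect="plink_raw")
        assert gm.factor_ids == ["rs1_A", "rs2_C"]
        assert labels.labels.tolist() == [1, 0]  # PHENOTYPE 2=case, 1=control
        assert gm.missing_mask[1, 1]

    def test_environment_columns_allow_non_genotype_codes(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("snpA\tAge\tclass\n0\t2\t1\n1\t0\t0\n")
        gm, _ = read_genotype_table(path, environment_columns=["Age"])
        assert gm.factor_kinds == [SNP, ENVIRONMENT]

    def test_duplicate_factor_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(["a", "a"], [SNP, SNP], np.zeros((2, 2), dtype=int))


class TestMissingness:
    def test_filter_thresholds_are_strict(self):
        # 4 samples: 25% missing removed, exactly 20% retained needs 5 samples
        missing = np.zeros((5, 3), dtype=bool)
        missing[0, 0] = True                       # 20% -> retained
        missing[[0, 1], 1] = True                  # 40% -> removed
        gm = make_matrix(np.zeros((5, 3), dtype=int), missing=missing)
        kept = filter_by_missingness(gm, max_rate=0.20)
        assert kept.factor_ids == ["snp1", "snp3"]

    def test_filter_is_idempotent(self):
        missing = np.zeros((4, 2), dtype=bool)
        missing[:3, 0] = True
        gm = make_matrix(np.zeros((4, 2), dtype=int), missing=missing)
        once = filter_by_missingness(gm)
        twice = filter_by_missingness(once)
        assert once.factor_ids == twice.factor_ids

    def test_empty_result_warns(self):
        gm = make_matrix(np.zeros((2, 1), dtype=int), missing=np.ones((2, 1), bool))
        with pytest.warns(UserWarning):
            out = filter_by_missingness(gm, max_rate=0.2)
        assert out.n_factors == 0

    @pytest.mark.parametrize(
        "column,expected",
        [([0, 0, 1, -1], 0), ([0, 0, 1, 1, -1], 0), ([2, 2, 1, -1], 2)],
    )
    def test_mode_imputation_breaks_ties_to_smaller_code(self, column, expected):
        col = np.array(column)
        missing = (col < 0)[:, None]
        gm = make_matrix(np.where(col < 0, 0, col)[:, None], missing=missing)
        filled = impute_mode(gm)
        assert filled.values[-1, 0] == expected
        assert not filled.missing_mask.any()

    def test_impute_without_missing_is_identity(self):
        gm = make_matrix([[0, 1], [2, 1]])
        assert (impute_mode(gm).values == gm.values).all()

    def test_all_missing_column_is_an_error(self):
        gm = make_matrix(np.zeros((2, 1), dtype=int), missing=np.ones((2, 1), bool))
        with pytest.raises(ValueError, match="missing"):
            impute_mode(gm)


class TestAllelicChi2:
    def test_equal_allele_frequencies_give_null_result(self):
        g = np.array([0, 1, 2, 0, 1, 2])
        labels = PhenotypeLabels(np.array([1, 1, 1, 0, 0, 0]))
        stat, p, df = allelic_chi2(g, labels)
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_hand_computed_2x2_example(self):
        # cases: 10x AA + 10x Aa -> (A=30, a=10); controls mirrored
        g = np.array([2] * 10 + [1] * 10 + [1] * 10 + [0] * 10)
        labels = PhenotypeLabels(np.array([1] * 20 + [0] * 20))
        stat, p, _ = allelic_chi2(g, labels)
        # Pearson on [[30,10],[10,30]]: all expected 20 -> 4 * 100/20 = 20
        assert stat == pytest.approx(20.0)
        assert 0 < p < 1e-4

    def test_matches_scipy_contingency_oracle(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=60)
        y = np.array([1] * 30 + [0] * 30)
        labels = PhenotypeLabels(y)
        stat, p, _ = allelic_chi2(g, labels)
        table = np.array(
            [
                [g[y == 1].sum(), (2 - g[y == 1]).sum()],
                [g[y == 0].sum(), (2 - g[y == 0]).sum()],
            ]
        )
        expected = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_monomorphic_snp_is_degenerate(self):
        labels = PhenotypeLabels(np.array([1, 1, 0, 0]))
        stat, p, _ = allelic_chi2(np.zeros(4, dtype=int), labels)
        assert stat == 0.0 and p == 1.0

    def test_invariant_to_order_and_label_swap(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        stat, _, _ = allelic_chi2(g, PhenotypeLabels(y))
        perm = rng.permutation(40)
        stat_perm, _, _ = allelic_chi2(g[perm], PhenotypeLabels(y[perm]))
        stat_swap, _, _ = allelic_chi2(g, PhenotypeLabels(1 - y))
        assert stat == pytest.approx(stat_perm) == pytest.approx(stat_swap)

    def test_association_filter_keeps_significant_snps(self):
        y = np.array([1] * 20 + [0] * 20)
        strong = np.array([2] * 18 + [1] * 2 + [0] * 18 + [1] * 2)
        flat = np.array([0, 1, 2, 1] * 10)
        gm = make_matrix(np.column_stack([strong, flat]))
        kept = filter_by_association(gm, PhenotypeLabels(y))
        assert kept.factor_ids == ["snp1"]


class TestDiscretizeAge:
    def test_boundaries_are_inclusive(self):
        # mean 60, population sd exactly 10: categories split at 55 and 65
        c = np.sqrt(175.0)
        ages = [60 - c, 60 + c, 55.0, 65.0]
        cats = discretize_age(ages)
        assert cats.tolist() == ["young", "elderly", "young", "elderly"]

    def test_middle_band_is_medium(self):
        ages = [50.0, 50.0, 70.0, 70.0, 60.0]  # mean 60, sd ~8.9
        cats = discretize_age(ages)
        assert cats[-1] == "medium"

    def test_every_sample_gets_exactly_one_category(self):
        rng = np.random.default_rng(0)
        ages = rng.normal(60, 12, size=200)
        cats = discretize_age(ages)
        counts = {c: (cats == c).sum() for c in ("young", "medium", "elderly")}
        assert sum(counts.values()) == 200
        assert all(v > 0 for v in counts.values())

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize_age([50.0, 50.0])


class TestFactorValueSpec:
    def test_rejects_duplicate_levels(self):
        with pytest.raises(ValueError):
            FactorValueSpec("Sex", (0, 0))

    def test_named_levels_must_align(self):
        with pytest.raises(ValueError):
            FactorValueSpec("Age", (0, 1, 2), ("young", "old"))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    data=st.data(),
    m=st.integers(min_value=2, max_value=8),
    n=st.integers(min_value=1, max_value=5),
)
def test_write_read_roundtrip_property(tmp_path_factory, data, m, n):
    """Any valid matrix survives a write/read cycle exactly."""
    values = np.array(
        [[data.draw(st.integers(0, 2)) for _ in range(n)] for _ in range(m)]
    )
    missing = np.array(
        [[data.draw(st.booleans()) for _ in range(n)] for _ in range(m)]
    )
    labels = np.array([data.draw(st.integers(0, 1)) for _ in range(m)])
    labels[0], labels[-1] = 0, 1
    gm = make_matrix(values, missing=missing)
    pl = PhenotypeLabels(labels)
    path = tmp_path_factory.mktemp("rt") / "d.tsv"
    write_genotype_table(gm, pl, path)
    gm2, pl2 = read_genotype_table(path)
    assert gm2.factor_ids == gm.factor_ids
    assert (gm2.missing_mask == gm.missing_mask).all()
    assert (gm2.values[~missing] == gm.values[~missing]).all()
    assert (pl2.labels == pl.labels).all()
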