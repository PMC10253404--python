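import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flavocap import (
    AbundanceMatrix,
    ConfigurationError,
    Contrast,
    ValidationError,
    aggregate_abundance,
    anova_pvalue,
    filter_min_peptides,
    group_ratio,
    normalize_abundance,
)
from .oracles import anova_f_and_p


def _report(rows):
    return pd.DataFrame(
        rows, columns=["peptide_id", "protein_accession", "sample_id", "intensity"]
    )


class TestAggregate:
    def test_sums_unique_peptide_intensities(self):
        rep = _report([("p1", "P", "S", 100.0), ("p2", "P", "S", 200.0)])
        m = aggregate_abundance(rep, {"P"})
        assert m.abundance.loc["P", "S"] == 300.0
        assert m.peptide_counts.loc["P", "S"] == 2

    def test_shared_peptides_contribute_to_no_protein(self):
        rep = _report(
            [("p1", "P1", "S", 100.0), ("p2", "P1;P2", "S", 500.0), ("p3", "P2", "S", 50.0)]
        )
        m = aggregate_abundance(rep, {"P1", "P2"})
        assert m.abundance.loc["P1", "S"] == 100.0
        assert m.abundance.loc["P2", "S"] == 50.0

    def test_unobserved_is_missing_not_zero(self):
        rep = _report([("p1", "P1", "S1", 100.0), ("p2", "P2", "S2", 80.0)])
        m = aggregate_abundance(rep, {"P1", "P2"})
        assert np.isnan(m.abundance.loc["P1", "S2"])
        assert m.peptide_counts.loc["P1", "S2"] == 0

    def test_unknown_accession_is_listed(self):
        rep = _report([("p1", "MYSTERY", "S", 1.0)])
        with pytest.raises(ValidationError, match="MYSTERY"):
            aggregate_abundance(rep, {"P1"})

    def test_row_order_permutation_invariant(self, small_report, small_truth):
        catalog = set(small_truth.catalog["accession"])
        m1 = aggregate_abundance(small_report, catalog)
        shuffled = small_report.sample(frac=1.0, random_state=9).reset_index(drop=True)
        m2 = aggregate_abundance(shuffled, catalog)
        pd.testing.assert_frame_equal(
            m1.abundance.sort_index(), m2.abundance.sort_index()
        )


class TestNormalize:
    def test_column_totals_equal_grand_mean(self):
        ab = pd.DataFrame({"A": [600.0, 400.0], "B": [1500.0, 500.0]}, index=["P1", "P2"])
        m = normalize_abundance(AbundanceMatrix(ab, ab.notna().astype(int)))
        totals = m.abundance.sum()
        assert totals["A"] == pytest.approx(1500.0)
        assert totals["B"] == pytest.approx(1500.0)

    def test_within_sample_ratios_preserved_and_idempotent(self):
        rng = np.random.default_rng(2)
        ab = pd.DataFrame(rng.lognormal(10, 1, size=(30, 4)), columns=list("ABCD"))
        ab.iloc[rng.random(ab.shape) < 0.2] = np.nan
        m0 = AbundanceMatrix(ab, ab.notna().astype(int))
        m1 = normalize_abundance(m0)
        ratio0 = (m0.abundance.iloc[0] / m0.abundance.iloc[1]).dropna()
        ratio1 = (m1.abundance.iloc[0] / m1.abundance.iloc[1]).dropna()
        pd.testing.assert_series_equal(ratio0, ratio1)
        m2 = normalize_abundance(m1)
        assert np.allclose(m1.abundance, m2.abundance, rtol=1e-9, equal_nan=True)

    def test_all_missing_sample_is_an_error(self):
        ab = pd.DataFrame({"A": [1.0, 2.0], "B": [np.nan, np.nan]}, index=["P1", "P2"])
        with pytest.raises(ValidationError, match="B"):
            normalize_abundance(AbundanceMatrix(ab, ab.notna().astype(int)))


class TestMinPeptideFilter:
    def _matrix(self):
        ab = pd.DataFrame({"S1": [10.0, 5.0, 7.0], "S2": [11.0, np.nan, 6.0]},
                          index=["P3pep", "P1pep", "P2pep"])
        counts = pd.DataFrame({"S1": [3, 1, 1], "S2": [3, 0, 2]}, index=ab.index)
        return AbundanceMatrix(ab, counts)

    def test_single_peptide_proteins_dropped_at_default_k(self):
        m = filter_min_peptides(self._matrix(), k=2)
        assert set(m.proteins) == {"P3pep", "P2pep"}

    def test_k_one_keeps_everything(self):
        m = filter_min_peptides(self._matrix(), k=1)
        assert len(m.proteins) == 3

    def test_max_rule_retains_protein_seen_well_once(self):
        ab = pd.DataFrame({"S1": [9.0], "S2": [np.nan]}, index=["P"])
        counts = pd.DataFrame({"S1": [3], "S2": [0]}, index=["P"])
        m = filter_min_peptides(AbundanceMatrix(ab, counts), k=2)
        assert m.proteins == ["P"]

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            filter_min_peptides(self._matrix(), k=0)


class TestGroupRatio:
    def test_ratio_of_group_means(self, tiny_matrix):
        contrast = Contrast(tiny_matrix.capture_samples, tiny_matrix.control_samples, "cap")
        out = group_ratio(tiny_matrix, contrast)
        assert out.loc["P_enriched", "r"] == pytest.approx(400.0 / 100.0)

    def test_absent_in_denominator_is_flag_not_inf(self, tiny_matrix):
        contrast = Contrast(tiny_matrix.capture_samples, tiny_matrix.control_samples, "cap")
        out = group_ratio(tiny_matrix, contrast)
        row = out.loc["P_absent_ctrl"]
        assert row["absent_in_denominator"]
        assert np.isnan(row["r"])

    def test_identical_groups_give_unity(self):
        ab = pd.DataFrame({"A1": [5.0], "A2": [5.0], "B1": [5.0], "B2": [5.0]}, index=["P"])
        m = AbundanceMatrix(ab, ab.notna().astype(int))
        out = group_ratio(m, Contrast(["A1", "A2"], ["B1", "B2"], "x"))
        assert out.loc["P", "r"] == 1.0

    def test_forward_times_reversed_is_unity(self, tiny_matrix):
        c = Contrast(tiny_matrix.capture_samples, tiny_matrix.control_samples, "cap")
        fwd = group_ratio(tiny_matrix, c)["r"]
        rev = group_ratio(tiny_matrix, c.reversed())["r"]
        prod = (fwd * rev).dropna()
        assert np.allclose(prod, 1.0)

    def test_median_center_switch(self, tiny_matrix):
        c = Contrast(tiny_matrix.capture_samples, tiny_matrix.control_samples, "cap")
        out = group_ratio(tiny_matrix, c, center="median")
        assert out.loc["P_enriched", "r"] == pytest.approx(400.0 / 100.0)


class TestAnova:
    def test_matches_first_principles_oracle(self):
        groups = [[10.0, 12.0, 11.0], [5.0, 6.0, 7.0]]
        ab = pd.DataFrame(
            {f"g{i}s{j}": [2.0 ** v] for i, g in enumerate(groups) for j, v in enumerate(g)},
            index=["P"],
        )
        m = AbundanceMatrix(ab, ab.notna().astype(int))
        ids = [[f"g{i}s{j}" for j in range(3)] for i in range(2)]
        out = anova_pvalue(m, ids, log_transform=True)
        f_exp, p_exp = anova_f_and_p(groups)
        assert out.loc["P", "F"] == pytest.approx(f_exp, rel=1e-10)
        assert out.loc["P", "p"] == pytest.approx(p_exp, rel=1e-10)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(10, 1, 4), rng.normal(11, 1, 5)
        ab = pd.DataFrame(
            {f"a{i}": [2.0 ** v] for i, v in enumerate(a)} | {f"b{i}": [2.0 ** v] for i, v in enumerate(b)},
            index=["P"],
        )
        m = AbundanceMatrix(ab, ab.notna().astype(int))
        out = anova_pvalue(m, [[f"a{i}" for i in range(4)], [f"b{i}" for i in range(5)]])
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert out.loc["P", "F"] == pytest.approx(t ** 2, rel=1e-9)
        assert out.loc["P", "p"] == pytest.approx(p_t, rel=1e-9)

    def test_zero_variance_is_flagged_undefined(self):
        ab = pd.DataFrame(
            {"a1": [4.0], "a2": [4.0], "b1": [4.0], "b2": [4.0]}, index=["P"]
        )
        m = AbundanceMatrix(ab, ab.notna().astype(int))
        out = anova_pvalue(m, [["a1", "a2"], ["b1", "b2"]])
        assert np.isnan(out.loc["P", "p"])
        assert out.loc["P", "flag"] == "zero_variance"

    def test_insufficient_replicates_flagged(self):
        ab = pd.DataFrame({"a1": [4.0], "a2": [5.0], "b1": [6.0], "b2": [np.nan]}, index=["P"])
        m = AbundanceMatrix(ab, ab.notna().astype(int))
        out = anova_pvalue(m, [["a1", "a2"], ["b1", "b2"]])
        assert np.isnan(out.loc["P", "p"])
        assert out.loc["P", "flag"] == "insufficient_replicates"

    def test_fewer_than_two_groups_errors(self, tiny_matrix):
        with pytest.raises(ConfigurationError):
            anova_pvalue(tiny_matrix, [tiny_matrix.capture_samples])

    def test_type_one_error_calibrated_under_null(self):
        """~5% of null proteins should reach p < 0.05 (3 vs 3 normal draws)."""
        rng = np.random.default_rng(17)
        vals = rng.normal(20, 1, size=(1000, 6))
        ab = pd.DataFrame(2.0 ** vals, columns=[f"s{i}" for i in range(6)])
        m = AbundanceMatrix(ab, ab.notna().astype(int))
        out = anova_pvalue(m, [[f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]])
        assert (out["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
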