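"""Bias measures, the exact sign test, and profile clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cognatebias import (
    AMINO_ACIDS,
    EnzymeAnnotation,
    Proteome,
    bias_matrix,
    bias_table,
    cluster_profiles,
    composition_bias,
    compute_m,
    compute_n,
    count_cognate,
    sign_test,
    sign_test_summary,
)


def _proteome(*seqs, organism_id="org1"):
    return Proteome(organism_id=organism_id,
                    proteins=tuple((f"p{i}", s) for i, s in enumerate(seqs)))


class TestCounting:
    @pytest.mark.parametrize("seq,aa,expected", [
        ("WWACK", "W", 2),
        ("wwack", "W", 2),                    # case-insensitive
        ("TRPSYNTHASEALPHA", "W", 0),         # no tryptophan at all
        ("AXBZUA", "A", 2),                   # ambiguity codes never match
    ])
    def test_cognate_counts(self, seq, aa, expected):
        assert count_cognate(seq, aa) == expected

    def test_each_standard_residue_counted_once(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        for aa in AMINO_ACIDS:
            assert count_cognate(seq, aa) == 1

    def test_count_rejects_empty_or_nonstandard_target(self):
        with pytest.raises(ValueError):
            count_cognate("", "A")
        with pytest.raises(ValueError):
            count_cognate("ACD", "X")

    def test_proteome_average_is_unweighted_by_length(self):
        prot = _proteome("A" * 10 + "G" * 90, "A" * 22 + "G" * 2)
        assert compute_m(prot, "A") == pytest.approx(16.0)
        prot_same = _proteome("ACAC", "ACAC", "ACAC")
        assert compute_m(prot_same, "A") == 2.0


class TestFinalEnzymeCount:
    def test_minimum_over_alternative_pathways(self):
        prot = _proteome("A" * 5 + "G", "A" * 9 + "G", "GGG")
        anns = [EnzymeAnnotation("org1", "p0", "A", "pw1"),
                EnzymeAnnotation("org1", "p1", "A", "pw2")]
        assert compute_n(prot, anns, "A") == 5

    def test_missing_when_no_annotation(self):
        prot = _proteome("AAA")
        assert compute_n(prot, [], "A") is None

    def test_zero_count_enzyme_is_valid(self):
        prot = _proteome("GGGG")
        anns = [EnzymeAnnotation("org1", "p0", "W", "pw")]
        assert compute_n(prot, anns, "W") == 0

    def test_dangling_annotation_skipped_with_warning(self, caplog):
        prot = _proteome("AAAG")
        anns = [EnzymeAnnotation("org1", "missing", "A", "pw"),
                EnzymeAnnotation("org1", "p0", "A", "pw")]
        with caplog.at_level("WARNING"):
            assert compute_n(prot, anns, "A") == 3
        assert "missing" in caplog.text


class TestCompositionBias:
    def test_over_and_under_representation(self):
        assert composition_bias(_proteome("L" * 7 + "G" * 93), "L") == pytest.approx(2.0)
        assert composition_bias(_proteome("G" * 40), "W") == pytest.approx(-2.0)

    def test_count_based_measure_differs_from_percentage_measure(self):
        # three proteins of lengths 100/200/400, two cognate residues each:
        # identical count contributions but 2% / 1% / 0.5% by composition
        seqs = ["AA" + "G" * 98, "AA" + "G" * 198, "AA" + "G" * 398]
        counts = [count_cognate(s, "A") for s in seqs]
        assert counts == [2, 2, 2]
        percentages = [c / len(s) for c, s in zip(counts, seqs)]
        assert percentages == pytest.approx([0.02, 0.01, 0.005])
        assert len(set(percentages)) == 3


class TestBiasTable:
    def test_definitional_identities_and_missing_flags(self):
        prot = _proteome("AAAG", "AG", "WGGA")
        anns = [EnzymeAnnotation("org1", "p1", "A", "pw")]
        table = bias_table([prot], anns)
        row_a = table[(table.aa == "A")].iloc[0]
        assert row_a["n"] == 1 and row_a["m"] == pytest.approx(5.0 / 3.0)
        assert row_a["cognate_bias"] == pytest.approx(row_a["n"] - row_a["m"])
        assert row_a["critical_bias"] == pytest.approx(row_a["cognate_bias"] - row_a["m"])
        row_w = table[(table.aa == "W")].iloc[0]
        assert row_w["n_missing"] and np.isnan(row_w["cognate_bias"])

    def test_matrix_layout_and_missing_cells(self):
        prot1 = _proteome("AAAG", organism_id="o1")
        prot2 = _proteome("AAG", organism_id="o2")
        anns = [EnzymeAnnotation("o1", "p0", "A", "pw")]
        mat = bias_matrix(bias_table([prot1, prot2], anns), "cognate_bias")
        assert mat.shape == (2, 20)
        assert list(mat.columns) == list(AMINO_ACIDS)
        assert not np.isnan(mat.loc["o1", "A"])
        assert np.isnan(mat.loc["o2", "A"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bias_matrix(pd.DataFrame())


class TestSignTest:
    def test_all_negative_closed_form(self):
        res = sign_test([-1.0] * 10, direction="low")
        assert res.p_value == pytest.approx(2.0 ** -10)
        assert res.n_negative == 10 and res.n_ties_dropped == 0

    def test_six_of_ten_negative_closed_form(self):
        values = [-1] * 6 + [1] * 4
        res = sign_test(values, direction="low")
        expected = sum(math.comb(10, k) for k in range(6, 11)) / 2 ** 10
        assert res.p_value == pytest.approx(expected)
        assert res.p_value == pytest.approx(0.376953125)

    def test_symmetric_sample_not_significant(self):
        values = [v for x in range(1, 11) for v in (x, -x)]
        assert sign_test(values, direction="low").p_value > 0.05
        assert sign_test(values, direction="high").p_value > 0.05

    def test_ties_dropped_and_all_ties_error(self):
        res = sign_test([0.0, 0.0, -1.0, -2.0], direction="low")
        assert res.n_ties_dropped == 2
        assert res.p_value == pytest.approx(0.25)
        with pytest.raises(ValueError):
            sign_test([0.0, 0.0])

    def test_auto_direction_follows_sample_median(self):
        assert sign_test([-3, -2, -1, 1], direction="auto").direction == "low"
        assert sign_test([3, 2, 1, -1], direction="auto").direction == "high"

    def test_matches_exhaustive_enumeration_small_n(self):
        # oracle: enumerate every sign pattern; p = share of patterns with
        # at least as many negatives as observed
        for N in (3, 6, 9):
            patterns = list(itertools.product([-1.0, 1.0], repeat=N))
            for k in range(0, N + 1):
                values = [-1.0] * k + [1.0] * (N - k)
                if k == 0 and N == 0:
                    continue
                p_obs = sign_test(values, direction="low").p_value
                p_enum = sum(1 for pat in patterns
                             if sum(v < 0 for v in pat) >= k) / len(patterns)
                assert p_obs == pytest.approx(p_enum, rel=1e-12)

    def test_summary_flags_injected_low_bias(self, recovery_cohort):
        summary = sign_test_summary(recovery_cohort["table"],
                                    measure="cognate_bias", direction="auto")
        w = summary.set_index("amino_acid").loc["W"]
        assert w["direction"] == "low" and w["significant"]
        r = summary.set_index("amino_acid").loc["R"]
        assert r["direction"] == "high" and r["significant"]


class TestClustering:
    def test_identical_rows_merge_at_zero_distance(self):
        mat = pd.DataFrame([[1.0] * 20, [1.0] * 20, [5.0] * 20],
                           index=["a", "b", "c"], columns=list(AMINO_ACIDS))
        res = cluster_profiles(mat)
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_nearest_pair_merges_first(self):
        base = np.zeros(20)
        mat = pd.DataFrame([base, base + 0.05, base + 10.0],
                           index=["a", "b", "c"], columns=list(AMINO_ACIDS))
        res = cluster_profiles(mat)
        first = set(res.row_linkage[0, :2].astype(int))
        assert first == {0, 1}

    def test_single_row_rejected(self):
        mat = pd.DataFrame([[0.0] * 20], index=["a"], columns=list(AMINO_ACIDS))
        with pytest.raises(ValueError):
            cluster_profiles(mat)

    def test_missing_cells_imputed_with_column_mean(self):
        mat = pd.DataFrame([[1.0] * 20, [3.0] * 20, [np.nan] + [2.0] * 19],
                           index=["a", "b", "c"], columns=list(AMINO_ACIDS))
        res = cluster_profiles(mat)
        assert res.imputed.loc["c", "A"] == pytest.approx(2.0)
        assert not res.imputed.isna().any().any()

    def test_two_environment_groups_recovered(self, two_group_cohort):
        from scipy.cluster.hierarchy import fcluster
        mat = bias_matrix(two_group_cohort["table"], "cognate_bias")
        res = cluster_profiles(mat)
        labels = fcluster(res.row_linkage, 2, criterion="maxclust")
        groups = two_group_cohort["groups"]
        agreement = max(np.mean(labels - 1 == groups), np.mean(labels - 1 == 1 - groups))
        assert agreement >= 0.95
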