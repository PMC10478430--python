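"""Heterogeneity scoring, background classification and paired discordance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metconcord import heterogeneity as het
from metconcord.cohort import MutationCall, TumourPairRecord
from metconcord.errors import DomainError, ValidationError


class TestHeterogeneityScore:
    @pytest.mark.parametrize("maf,tc,expected", [
        (0.30, 60, 1.00),
        (0.20, 80, 0.50),
        (0.0, 70, 0.0),
    ])
    def test_formula(self, maf, tc, expected):
        assert het.heterogeneity_score(maf, tc) == pytest.approx(expected)

    @given(maf=st.floats(0.01, 0.45), tc=st.floats(10, 100))
    def test_homogeneity_in_maf_and_tc(self, maf, tc):
        hs = het.heterogeneity_score(maf, tc)
        assert het.heterogeneity_score(2 * maf, tc) == pytest.approx(2 * hs)
        assert het.heterogeneity_score(maf, tc / 2) == pytest.approx(2 * hs)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            het.heterogeneity_score(0.3, 0)
        with pytest.raises(ValidationError):
            het.heterogeneity_score(1.2, 50)

    def test_values_above_two_are_legal(self):
        assert het.heterogeneity_score(0.99, 40) == pytest.approx(4.95)


class TestClassifyBackground:
    @pytest.mark.parametrize("hs,expected", [
        (0.0, "WT"),
        (0.94, "STC"),
        (0.95, "ATC"),
        (1.00, "ATC"),
        (1.05, "ATC"),
        (1.0500001, "CNV"),
        (1.50, "CNV"),
        (1e-9, "STC"),
    ])
    def test_band_assignment(self, hs, expected):
        assert het.classify_background(hs) == expected

    @given(maf=st.floats(0, 1), tc=st.floats(0.5, 100))
    def test_score_then_classify_partitions_the_domain(self, maf, tc):
        hs = het.heterogeneity_score(maf, tc)
        status = het.classify_background(hs)
        assert status in ("WT", "STC", "ATC", "CNV")
        assert (status == "WT") == (hs == 0)

    def test_negative_score_rejected(self):
        with pytest.raises(DomainError):
            het.classify_background(-0.1)


def _assessment(case, role, hs, gene="TP53", hgvs="c.1A>G"):
    return het.HeterogeneityAssessment(
        case_id=case, role=role, gene=gene, hgvs_c=hgvs, hs=hs,
        status=het.classify_background(hs))


class TestCompareLocus:
    def test_inter_status_change(self):
        c = het.compare_pair_locus(_assessment("c1", "primary", 0.6),
                                   _assessment("c1", "metastasis", 1.3))
        assert c.change_class == "inter_status"

    def test_intra_status_change(self):
        c = het.compare_pair_locus(_assessment("c1", "primary", 1.2),
                                   _assessment("c1", "metastasis", 1.9))
        assert c.change_class == "intra_status"
        assert c.delta_hs == pytest.approx(0.7)

    def test_no_change_below_threshold(self):
        c = het.compare_pair_locus(_assessment("c1", "primary", 1.2),
                                   _assessment("c1", "metastasis", 1.4))
        assert c.change_class == "none"

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValidationError):
            het.compare_pair_locus(_assessment("c1", "primary", 1.2),
                                   _assessment("c2", "metastasis", 1.2))


def _synthetic_comparisons(n_inter, n_intra, n_none):
    comparisons = []
    for i in range(n_inter):
        comparisons.append(het.compare_pair_locus(
            _assessment(f"i{i}", "primary", 0.6),
            _assessment(f"i{i}", "metastasis", 1.3)))
    for i in range(n_intra):
        comparisons.append(het.compare_pair_locus(
            _assessment(f"j{i}", "primary", 1.2),
            _assessment(f"j{i}", "metastasis", 1.9)))
    for i in range(n_none):
        comparisons.append(het.compare_pair_locus(
            _assessment(f"k{i}", "primary", 1.2),
            _assessment(f"k{i}", "metastasis", 1.3)))
    return comparisons


class TestDiscordanceSummary:
    def test_reproduces_published_proportion_test(self):
        summary = het.discordance_summary(
            _synthetic_comparisons(22, 19, 17), rounding="three_decimals")
        assert (summary.discordant, summary.denominator) == (41, 58)
        assert summary.test.z == pytest.approx(6.927, abs=5e-4)
        assert summary.test.difference == pytest.approx(0.414, abs=5e-4)

    def test_all_none_is_zero_fraction_with_maximal_negative_z(self):
        summary = het.discordance_summary(_synthetic_comparisons(0, 0, 5))
        assert summary.discordant == 0
        assert summary.test.z == -math.inf

    def test_all_discordant_is_full_fraction(self):
        summary = het.discordance_summary(_synthetic_comparisons(3, 2, 0))
        assert summary.discordant == summary.denominator == 5
        assert summary.test.z == math.inf

    def test_denominator_policies(self):
        comparisons = _synthetic_comparisons(2, 1, 1)
        # one extra locus wild-type in the primary (a metastasis-private
        # mutation): counted under union but not under primary loci
        comparisons.append(het.compare_pair_locus(
            _assessment("w1", "primary", 0.0),
            _assessment("w1", "metastasis", 0.6)))
        primary = het.discordance_summary(comparisons, "primary_loci")
        union = het.discordance_summary(comparisons, "union_loci")
        assert primary.denominator == 4
        assert union.denominator == 5
        assert union.discordant == primary.discordant + 1

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            het.discordance_summary([])


class TestMutationConcordance:
    def test_table1_counts_all_hold_simultaneously(self, table1_calls):
        calls, _ = table1_calls
        conc = het.mutation_concordance(calls)
        assert conc == {
            "total_loci": 60,
            "identical_loci": 54,
            "private_primary": 4,
            "private_metastasis": 2,
            "mutations_primary": 58,
            "mutations_metastasis": 56,
        }

    def test_single_pair_cases(self):
        both = [MutationCall("c1", r, "TP53", "c.1A>G", present=True)
                for r in ("primary", "metastasis")]
        assert het.mutation_concordance(both)["identical_loci"] == 1
        private = [
            MutationCall("c1", "primary", "TP53", "c.1A>G", present=True),
            MutationCall("c1", "metastasis", "TP53", "c.1A>G", present=False),
        ]
        conc = het.mutation_concordance(private)
        assert conc["identical_loci"] == 0
        assert conc["private_primary"] == 1

    def test_one_role_only_rejected(self):
        calls = [MutationCall("c1", "primary", "TP53", "c.1A>G", present=True)]
        with pytest.raises(ValidationError):
            het.mutation_concordance(calls)


class TestGeneFrequencies:
    def test_table1_gene_statistics(self, table1_calls):
        calls, case_ids = table1_calls
        freqs = het.gene_frequencies(calls, case_ids).set_index("gene")
        assert freqs.loc["TP53", "case_percent"] == 86
        assert freqs.loc["TP53", "n_cases"] == 19
        assert freqs.loc["APC", "n_mutations"] == 18
        assert freqs.loc["KRAS", "n_mutations"] == 10
        assert freqs.loc["PIK3CA", "case_percent"] == 9
        assert freqs.loc["BRAF", "case_percent"] == 5  # 1/22 rounds to 5
        # the two mutation-free cases stay in the denominator
        assert len(case_ids) == 22

    def test_single_fully_mutated_case(self):
        calls = [MutationCall("c1", r, "KRAS", "c.35G>T", present=True)
                 for r in ("primary", "metastasis")]
        freqs = het.gene_frequencies(calls).set_index("gene")
        assert freqs.loc["KRAS", "case_percent"] == 100


class TestMafr:
    def _call(self, gene, maf, case="c1", role="primary", hgvs=None):
        return MutationCall(case, role, gene, hgvs or f"c.{gene}", present=True,
                            maf=maf)

    def test_branch_driver_relative_to_trunk(self):
        calls = [self._call("APC", 0.40), self._call("TP53", 0.20)]
        records = het.mafr_table(calls)
        by_gene = {r.gene: r for r in records}
        assert by_gene["TP53"].mafr == pytest.approx(0.5)
        assert by_gene["APC"].mafr == pytest.approx(1.0)
        assert by_gene["TP53"].reference_gene == "APC"

    def test_falls_back_to_branch_driver(self):
        calls = [self._call("TP53", 0.30), self._call("PIK3CA", 0.15)]
        by_gene = {r.gene: r for r in het.mafr_table(calls)}
        assert by_gene["PIK3CA"].mafr == pytest.approx(0.5)
        assert by_gene["PIK3CA"].reference_gene == "TP53"

    def test_sample_without_driver_is_skipped_with_warning(self):
        calls = [self._call("PIK3CA", 0.2), self._call("SMAD4", 0.1)]
        with pytest.warns(UserWarning, match="no driver"):
            assert het.mafr_table(calls) == []

    def test_matches_exhaustive_division_by_max_trunk_driver(self):
        rng = np.random.default_rng(5)
        genes = ["APC", "KRAS", "TP53", "PIK3CA", "SMAD4"]
        mafs = rng.uniform(0.05, 0.5, size=5)
        calls = [self._call(g, m, hgvs=f"c.{i}") for i, (g, m) in
                 enumerate(zip(genes, mafs))]
        trunk = {"APC", "KRAS", "NRAS", "BRAF"}
        ref = max((m for g, m in zip(genes, mafs) if g in trunk))
        got = {r.hgvs_c: r.mafr for r in het.mafr_table(calls)}
        for i, m in enumerate(mafs):
            assert got[f"c.{i}"] == pytest.approx(m / ref, abs=1e-12)


class TestCorrelatePairs:
    def test_identical_and_inverted_vectors(self):
        assert het.correlate_pairs([1, 2, 3], [1, 2, 3]).r == pytest.approx(1.0)
        assert het.correlate_pairs([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_recovers_designed_correlation(self):
        rng = np.random.default_rng(42)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        res = het.correlate_pairs(xy[:, 0], xy[:, 1])
        assert res.r == pytest.approx(0.8, abs=0.1)
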