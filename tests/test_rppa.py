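"""RPPA normalisation, SD-cutoff alteration calls and the pathway cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, binomtest

from metconcord import rppa as rp
from metconcord.errors import DomainError
from metconcord.simulate import SimulationDesign, generate_rppa_cohort


class TestRelativeExpression:
    def test_ratio_and_zero_signal(self):
        assert rp.relative_expression(10, 5) == pytest.approx(2.0)
        assert rp.relative_expression(0, 5) == 0.0

    def test_zero_total_protein_rejected(self):
        with pytest.raises(DomainError):
            rp.relative_expression(3, 0)


class TestTcNormaliseMet:
    @pytest.mark.parametrize("e_m,tc_p,tc_m,expected", [
        (1.0, 80, 60, 1.2),
        (2.0, 50, 70, 1.6),
        (3.5, 65, 65, 3.5),
    ])
    def test_delta_tc_correction(self, e_m, tc_p, tc_m, expected):
        assert rp.tc_normalise_met(e_m, tc_p, tc_m) == pytest.approx(expected)

    def test_linear_in_expression(self):
        a = rp.tc_normalise_met(1.0, 80, 60)
        assert rp.tc_normalise_met(3.0, 80, 60) == pytest.approx(3 * a)

    def test_cellularity_domain(self):
        with pytest.raises(DomainError):
            rp.tc_normalise_met(1.0, 0, 60)


class TestMarkerSd:
    def test_constant_and_two_point(self):
        assert rp.marker_sd([3, 3, 3]) == 0.0
        assert rp.marker_sd([0, 2]) == pytest.approx(np.sqrt(2))

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(size=40)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert rp.marker_sd(values) == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(DomainError):
            rp.marker_sd([1.0])


class TestAlterationCall:
    def test_strict_exceedance(self):
        assert rp.alteration_call("c", "m", 2.5, 1.0, 1.0).altered
        assert not rp.alteration_call("c", "m", 2.0, 1.0, 1.0).altered  # tie
        assert not rp.alteration_call("c", "m", 1.0, 1.0, 1.0).altered

    def test_direction_relative_to_metastasis(self):
        assert rp.alteration_call("c", "m", 1.0, 3.0, 1.0).direction == "up"
        assert rp.alteration_call("c", "m", 3.0, 1.0, 1.0).direction == "down"

    def test_antisymmetric_under_role_swap(self):
        a = rp.alteration_call("c", "m", 3.2, 1.1, 1.0)
        b = rp.alteration_call("c", "m", 1.1, 3.2, 1.0)
        assert a.direction == "down" and b.direction == "up"
        assert abs(a.differential) == abs(b.differential)


def _call(case, marker, direction):
    e_p = {"up": 0.0, "none": 1.0, "down": 2.0}[direction]
    return rp.AlterationCall(case_id=case, marker=marker, e_primary=e_p,
                             e_metastasis_tc=1.0, sd=0.5, direction=direction)


class TestIsoformValidation:
    def test_identical_call_vectors_give_kappa_one(self):
        calls = [_call(f"c{i}", m, d)
                 for i, d in enumerate(["up", "none", "down"] * 4)
                 for m in ("PTEN", "phosphoPTEN")]
        res = rp.validate_isoform_concordance(calls, [("PTEN", "phosphoPTEN")])
        assert res[("PTEN", "phosphoPTEN")].kappa == pytest.approx(1.0)

    def test_independent_calls_give_near_zero_kappa(self):
        rng = np.random.default_rng(17)
        dirs = np.array(["up", "none", "down"])
        calls = []
        for i in range(1000):
            calls.append(_call(f"c{i}", "RAS", dirs[rng.integers(3)]))
            calls.append(_call(f"c{i}", "RASA1", dirs[rng.integers(3)]))
        res = rp.validate_isoform_concordance(calls, [("RAS", "RASA1")])
        assert abs(res[("RAS", "RASA1")].kappa) < 0.05

    def test_fully_discordant_pair_gives_nonpositive_kappa(self):
        calls = []
        for i, (d1, d2) in enumerate([("up", "down")] * 6 + [("down", "up")] * 6
                                     + [("none", "up")] * 3 + [("up", "none")] * 3):
            calls.append(_call(f"c{i}", "CD34", d1))
            calls.append(_call(f"c{i}", "CD31", d2))
        res = rp.validate_isoform_concordance(calls, [("CD34", "CD31")])
        assert res[("CD34", "CD31")].kappa <= 0

    def test_missing_marker_skipped_with_warning(self):
        calls = [_call("c1", "CD34", "up")]
        with pytest.warns(UserWarning, match="skipped"):
            res = rp.validate_isoform_concordance(calls, [("CD34", "CD31")])
        assert res == {}


class TestCollapseIsoforms:
    def test_any_member_alters_the_parent(self):
        calls = [_call("c1", "P85", "up"), _call("c1", "P110", "none")]
        collapsed = rp.collapse_isoforms(calls)
        assert bool(collapsed.loc["c1", "PI3K"])

    def test_union_is_idempotent_and_monotone(self):
        both = [_call("c1", "pAKT-ser", "up"), _call("c1", "pAKT-thr", "down")]
        one = both[:1]
        c_both = rp.collapse_isoforms(both)
        c_one = rp.collapse_isoforms(one)
        assert bool(c_both.loc["c1", "AKT"]) and bool(c_one.loc["c1", "AKT"])

    def test_unaltered_members_leave_parent_unaltered(self):
        calls = [_call("c1", "PTEN", "none"), _call("c1", "phosphoPTEN", "none")]
        assert not bool(rp.collapse_isoforms(calls).loc["c1", "PTEN"])


class TestPathwayCalls:
    def test_majority_rule(self):
        collapsed = pd.DataFrame(
            {"RAS": [True], "RASA1": [True], "pCRAF": [False]}, index=["c1"])
        calls = rp.pathway_calls(collapsed, {"RAS-RAF-MEK": ("RAS", "RASA1", "pCRAF")})
        assert calls[0].altered
        assert calls[0].altered_fraction == pytest.approx(2 / 3)

    def test_collapsed_pi3k_pathway_minority_not_altered(self):
        # only PTEN and AKT altered among the five collapsed markers: 2/5
        calls = [_call("c1", "PTEN", "up"), _call("c1", "phosphoPTEN", "up"),
                 _call("c1", "pAKT-ser", "down"), _call("c1", "pAKT-thr", "none"),
                 _call("c1", "P85", "none"), _call("c1", "P110", "none"),
                 _call("c1", "mtor", "none"), _call("c1", "pGSK", "none")]
        collapsed = rp.collapse_isoforms(calls)
        pcalls = rp.pathway_calls(
            collapsed, {"PI3K-AKT-PTEN": rp.DEFAULT_PATHWAY_MAP["PI3K-AKT-PTEN"]})
        assert pcalls[0].altered_fraction == pytest.approx(0.4)
        assert not pcalls[0].altered

    def test_singleton_pathway(self):
        collapsed = pd.DataFrame({"BCL2": [True]}, index=["c1"])
        calls = rp.pathway_calls(collapsed, {"apoptosis": ("BCL2",)})
        assert calls[0].altered and calls[0].altered_fraction == 1.0


class TestPairAndPopulation:
    def _pathway_calls(self, flags_by_case):
        return [rp.PathwayCall(case_id=c, pathway=f"p{i}", altered_fraction=1.0,
                               altered=flag)
                for c, flags in flags_by_case.items()
                for i, flag in enumerate(flags)]

    def test_sixteen_of_twenty_pairs(self):
        flags = {}
        for i in range(16):
            flags[f"c{i:02d}"] = [True, True, True, False, False, False]
        for i in range(16, 20):
            flags[f"c{i:02d}"] = [True, False, False, False, False, False]
        summary = rp.pair_and_population_summary(self._pathway_calls(flags))
        assert summary.population_fraction == pytest.approx(0.8)
        assert summary.population_different

    def test_no_alterations(self):
        flags = {f"c{i}": [False] * 6 for i in range(5)}
        summary = rp.pair_and_population_summary(self._pathway_calls(flags))
        assert not summary.population_different

    def test_inclusive_boundaries(self):
        flags = {"c1": [True] * 3 + [False] * 3, "c2": [False] * 6}
        summary = rp.pair_and_population_summary(self._pathway_calls(flags))
        assert bool(summary.pair_altered["c1"])
        assert summary.population_different  # exactly half the pairs


class TestEndToEndRecovery:
    @pytest.mark.parametrize("pi", [0.1, 0.5, 0.9])
    def test_population_fraction_within_binomial_interval(self, pi):
        """The realised altered-pair fraction matches the design-implied
        pair probability P(Binom(6, pi) >= 3) within the exact 95% CI."""
        design = SimulationDesign(
            n_pairs=200,
            rppa_pathway_probs={p: pi for p in rp.DEFAULT_PATHWAY_MAP},
        )
        measurements, pairs, _ = generate_rppa_cohort(design, seed=29)
        calls = rp.alteration_calls(measurements, pairs)
        collapsed = rp.collapse_isoforms(calls)
        pcalls = rp.pathway_calls(collapsed)
        summary = rp.pair_and_population_summary(pcalls)
        k = int(summary.pair_altered.sum())
        ci = binomtest(k, 200).proportion_ci(confidence_level=0.95,
                                             method="exact")
        p_design = float(1 - binom.cdf(2, 6, pi))
        assert ci.low <= p_design <= ci.high
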