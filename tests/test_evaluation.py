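"""Cohort evaluation: adequacy, Fisher's exact test, summaries."""
import itertools

import numpy as np
import pytest
from scipy import stats

from abxcascade.episode import CultureResult
from abxcascade.errors import UndefinedAdequacyError, ValidationError
from abxcascade.evaluate import (
    AdequacyRecord,
    changes_from_step_distribution,
    fisher_exact_two_sided,
    median_iqr,
    regimen_adequacy,
    summarize_cohort,
)


def isolate(panel, specimen="blood", relevant=True, eid="E1"):
    return CultureResult(
        episode_id=eid, specimen=specimen, clinically_relevant=relevant, panel=panel
    )


class TestAdequacy:
    def test_direct_match_is_adequate(self):
        iso = isolate({"ceftriaxone": "susceptible", "ciprofloxacin": "resistant"})
        assert regimen_adequacy({"ceftriaxone", "azithromycin"}, [iso])

    def test_resistant_to_all_agents_is_inadequate(self):
        iso = isolate({"ceftriaxone": "resistant", "meropenem": "resistant"})
        assert not regimen_adequacy({"ceftriaxone", "meropenem"}, [iso])

    def test_not_tested_never_counts_as_coverage(self):
        iso = isolate({"ceftriaxone": "not_tested"})
        assert not regimen_adequacy({"ceftriaxone"}, [iso])

    def test_irrelevant_isolates_ignored(self):
        relevant = isolate({"ceftriaxone": "susceptible"})
        contaminant = isolate({"ceftriaxone": "resistant"}, relevant=False)
        # contaminant panel may be empty for irrelevant isolates; here it is
        # populated but must still be ignored
        assert regimen_adequacy({"ceftriaxone"}, [relevant, contaminant])

    def test_no_relevant_isolate_is_undefined_not_false(self):
        with pytest.raises(UndefinedAdequacyError):
            regimen_adequacy({"ceftriaxone"}, [isolate({"x": "resistant"}, relevant=False)])

    def test_all_isolates_rule_by_exhaustive_two_isolate_enumeration(self):
        """Patient-level adequacy requires every relevant isolate covered:
        verified against brute-force conjunction over all 2-isolate panels."""
        results = ["susceptible", "resistant", "not_tested"]
        regimen = {"ceftriaxone", "meropenem"}
        for p1 in itertools.product(results, repeat=2):
            for p2 in itertools.product(results, repeat=2):
                iso1 = isolate({"ceftriaxone": p1[0], "meropenem": p1[1]})
                iso2 = isolate({"ceftriaxone": p2[0], "meropenem": p2[1]}, specimen="non_blood")
                expected = all(
                    any(r == "susceptible" for r in p) for p in (p1, p2)
                )
                assert regimen_adequacy(regimen, [iso1, iso2]) == expected

    def test_monotone_in_regimen_breadth(self):
        """Adding an agent never flips adequacy from adequate to inadequate."""
        rng = np.random.default_rng(1)
        agents = ["ciprofloxacin", "ceftriaxone", "ceftazidime", "meropenem"]
        for _ in range(200):
            panel = {a: ("susceptible" if rng.random() < 0.5 else "resistant") for a in agents}
            iso = isolate(panel)
            k = rng.integers(1, len(agents))
            base = set(rng.choice(agents, size=k, replace=False))
            wider = base | {agents[rng.integers(len(agents))]}
            if regimen_adequacy(base, [iso]):
                assert regimen_adequacy(wider, [iso])


class TestFisher:
    def test_identical_rows_give_p_one(self):
        res = fisher_exact_two_sided([[12, 5], [12, 5]])
        assert res.p_value == pytest.approx(1.0)
        assert not res.degenerate

    def test_two_by_two_with_unit_margins(self):
        # both tables with these margins have probability 1/2
        assert fisher_exact_two_sided([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)

    def test_perfect_separation_five_five(self):
        # exhaustive enumeration: only the two extreme tables qualify,
        # each with probability 1/C(10,5) = 1/252
        res = fisher_exact_two_sided([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252, rel=1e-12)

    def test_zero_margin_is_degenerate_p_one(self):
        res = fisher_exact_two_sided([[0, 0], [3, 4]])
        assert res.p_value == 1.0 and res.degenerate

    def test_symmetry_under_row_and_column_swaps(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 15, size=(2, 2))
            p = fisher_exact_two_sided(t).p_value
            assert fisher_exact_two_sided(t[::-1, :]).p_value == pytest.approx(p, rel=1e-9)
            assert fisher_exact_two_sided(t[:, ::-1]).p_value == pytest.approx(p, rel=1e-9)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2))
            ours = fisher_exact_two_sided(t)
            if ours.degenerate:
                continue
            _, p_scipy = stats.fisher_exact(t, alternative="two-sided")
            assert ours.p_value == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided([[1.5, 2], [3, 4]])


class TestMedianIQR:
    def test_published_de_escalation_distribution(self):
        steps = [1] * 15 + [2] * 29 + [3] * 7 + [4] * 1
        assert median_iqr(steps) == (2, 1, 2)

    def test_published_escalation_distribution(self):
        steps = [1] * 6 + [2] * 2 + [3] * 1 + [5] * 1
        median, q1, q3 = median_iqr(steps)
        assert (median, q1, q3) == (1, 1, 2)

    def test_odd_count_middle_value_shared_by_both_halves(self):
        # inclusive (median-of-halves) convention: quartiles of 1..5 are 2 and 4
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_singleton(self):
        assert median_iqr([7]) == (7, 7, 7)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            median_iqr([])


class TestSummarize:
    def test_category_proportions_sum_to_one(self):
        changes = changes_from_step_distribution({1: 3, 2: 2}, {1: 1}, no_change=4)
        summary = summarize_cohort(changes)
        assert sum(summary.proportions.values()) == pytest.approx(1.0)
        assert summary.counts == {"de_escalation": 5, "escalation": 1, "no_change": 4}

    def test_step_summaries_match_published_convention(self):
        changes = changes_from_step_distribution(
            {1: 15, 2: 29, 3: 7, 4: 1}, {1: 6, 2: 2, 3: 1, 5: 1}, no_change=45
        )
        summary = summarize_cohort(changes)
        assert summary.steps["de_escalation"] == (2, 1, 2)
        assert summary.steps["escalation"] == (1, 1, 2)
        assert summary.n == 107

    def test_all_no_change_leaves_step_summaries_absent(self):
        changes = changes_from_step_distribution({}, {}, no_change=5)
        summary = summarize_cohort(changes)
        assert summary.proportions == {
            "de_escalation": 0.0,
            "escalation": 0.0,
            "no_change": 1.0,
        }
        assert summary.steps["de_escalation"] is None
        assert summary.steps["escalation"] is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort([])

    def test_adequacy_strata_and_patient_exclusion(self):
        changes = changes_from_step_distribution({1: 2}, {}, no_change=1)
        records = [
            AdequacyRecord(
                episode_id="A",
                clinician_regimen=frozenset({"ceftriaxone"}),
                algorithm_regimen=frozenset({"ciprofloxacin"}),
                isolates=(
                    isolate({"ceftriaxone": "susceptible", "ciprofloxacin": "resistant"}),
                ),
            ),
            AdequacyRecord(
                episode_id="B",
                clinician_regimen=frozenset({"meropenem"}),
                algorithm_regimen=frozenset({"meropenem"}),
                isolates=(
                    isolate({"meropenem": "susceptible"}, specimen="non_blood", eid="B"),
                ),
            ),
        ]
        summary = summarize_cohort(changes, records)
        blood = summary.adequacy["blood"]
        assert blood.table.as_tuple() == (1, 0, 0, 1)
        non_blood = summary.adequacy["non_blood"]
        assert non_blood.table.as_tuple() == (1, 0, 1, 0)
        assert "both" not in summary.adequacy  # nobody has both specimen types

    def test_medians_lie_within_observed_step_range(self):
        changes = changes_from_step_distribution({1: 5, 4: 2}, {2: 3})
        summary = summarize_cohort(changes)
        med, q1, q3 = summary.steps["de_escalation"]
        assert 1 <= q1 <= med <= q3 <= 4
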