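"""Recommendation engine: thresholds, cascade walk, MRSA rule, composition."""
from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abxcascade.engine import (
    GPDirective,
    SeverityThresholds,
    apply_gp_rule,
    recommend,
    severity_threshold,
    walk_cascade,
)
from abxcascade.episode import MRSAScreen
from abxcascade.errors import ConfigurationError, ValidationError
from abxcascade.registry import default_registry

from conftest import T0, flat_model_set, make_episode

REGISTRY = default_registry()
CASCADE = REGISTRY.cascade

EXAMPLE_PROFILE = {
    "ciprofloxacin": 0.78,
    "ceftriaxone": 0.85,
    "ceftazidime": 0.88,
    "piperacillin-tazobactam": 0.92,
    "meropenem": 0.95,
}


class TestSeverityThreshold:
    @pytest.mark.parametrize(
        "qsofa, vaso, expected",
        [(0, False, 0.80), (1, False, 0.80), (2, False, 0.90), (3, False, 0.90),
         (0, True, 0.90), (1, True, 0.90)],
    )
    def test_default_mapping(self, qsofa, vaso, expected):
        assert severity_threshold(qsofa, vaso) == expected

    def test_alternative_reading_qsofa_two_low(self):
        # under the strict "> 2" reading, a qSOFA of 2 keeps the low threshold
        t = SeverityThresholds(qsofa_high_cutoff=3)
        assert severity_threshold(2, False, t) == 0.80
        assert severity_threshold(3, False, t) == 0.90
        assert severity_threshold(2, True, t) == 0.90

    def test_out_of_range_qsofa_rejected(self):
        with pytest.raises(ValidationError):
            severity_threshold(4, False)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            SeverityThresholds(low=0.95, high=0.90)


class TestWalkCascade:
    def test_narrowest_agent_meeting_low_threshold(self):
        sel = walk_cascade(EXAMPLE_PROFILE, 0.80, gp_required=False)
        assert sel.agent == "ceftriaxone" and not sel.shortfall

    def test_high_threshold_moves_up(self):
        sel = walk_cascade(EXAMPLE_PROFILE, 0.90, gp_required=False)
        assert sel.agent == "piperacillin-tazobactam"

    def test_gp_requirement_skips_agents_without_gp_coverage(self):
        profile = dict(EXAMPLE_PROFILE, ciprofloxacin=0.85)
        assert walk_cascade(profile, 0.80, gp_required=False).agent == "ciprofloxacin"
        sel = walk_cascade(profile, 0.80, gp_required=True)
        assert sel.agent == "ceftriaxone" and sel.gp_adjusted

    def test_no_qualifying_agent_returns_broadest_with_shortfall(self):
        profile = {a: 0.5 for a in CASCADE}
        sel = walk_cascade(profile, 0.90, gp_required=False)
        assert sel.agent == "meropenem" and sel.shortfall

    def test_exact_threshold_qualifies_weak_inequality(self):
        profile = {a: 0.5 for a in CASCADE}
        profile["ciprofloxacin"] = 0.80
        assert walk_cascade(profile, 0.80, gp_required=False).agent == "ciprofloxacin"
        sel = walk_cascade(profile, 0.80, gp_required=False, strict=True)
        assert sel.agent == "meropenem" and sel.shortfall

    def test_missing_profile_entry_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="meropenem"):
            walk_cascade({a: 0.9 for a in CASCADE[:-1]}, 0.8, False)

    def brute_force(self, profile, threshold, gp_required):
        """Independent oracle: filter agents by threshold (and GP flag),
        take the minimum cascade position; GP-fallback logic mirrored by
        exhaustive scan rather than a walk."""
        ok = [a for a in CASCADE if profile[a] >= threshold]
        if not ok:
            pool = [a for a in CASCADE if REGISTRY.has_gp_coverage(a)] if gp_required else CASCADE
            return (pool or CASCADE)[-1], True
        if not gp_required:
            return ok[0], False
        start = CASCADE.index(ok[0])
        gp_ok = [a for a in ok if CASCADE.index(a) >= start and REGISTRY.has_gp_coverage(a)]
        if gp_ok:
            return min(gp_ok, key=CASCADE.index), False
        gp_pool = [a for a in CASCADE if REGISTRY.has_gp_coverage(a)]
        return gp_pool[-1], True

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            profile = {a: float(p) for a, p in zip(CASCADE, rng.random(len(CASCADE)))}
            threshold = float(rng.uniform(0.05, 0.99))
            gp_required = bool(rng.random() < 0.5)
            sel = walk_cascade(profile, threshold, gp_required)
            agent, shortfall = self.brute_force(profile, threshold, gp_required)
            assert (sel.agent, sel.shortfall) == (agent, shortfall)

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
        t1=st.floats(0.05, 0.99),
        t2=st.floats(0.05, 0.99),
    )
    def test_threshold_monotonicity(self, ps, t1, t2):
        """Raising the threshold never narrows the recommendation."""
        profile = dict(zip(CASCADE, ps))
        lo, hi = min(t1, t2), max(t1, t2)
        a_lo = walk_cascade(profile, lo, gp_required=False).agent
        a_hi = walk_cascade(profile, hi, gp_required=False).agent
        assert REGISTRY.position(a_hi) >= REGISTRY.position(a_lo)

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
        idx=st.integers(0, 4),
        bump=st.floats(0.0, 1.0),
    )
    def test_profile_monotonicity(self, ps, idx, bump):
        """Increasing one agent's coverage never broadens the recommendation."""
        profile = dict(zip(CASCADE, ps))
        bumped = dict(profile)
        agent = CASCADE[idx]
        bumped[agent] = min(1.0, bumped[agent] + bump)
        before = walk_cascade(profile, 0.8, gp_required=False)
        after = walk_cascade(bumped, 0.8, gp_required=False)
        if not before.shortfall:
            assert REGISTRY.position(after.agent) <= REGISTRY.position(before.agent)

    @given(ps=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
           t=st.floats(0.05, 0.99))
    def test_gp_required_selection_carries_gp_flag(self, ps, t):
        sel = walk_cascade(dict(zip(CASCADE, ps)), t, gp_required=True)
        assert REGISTRY.has_gp_coverage(sel.agent)


class TestGPRule:
    def screen(self, result, days_ago):
        return MRSAScreen(result=result, collected=T0 - timedelta(days=days_ago))

    @pytest.mark.parametrize(
        "result, on_vanco, expected",
        [
            ("positive", False, GPDirective.ADD),
            ("positive", True, GPDirective.CONTINUE),
            ("negative", True, GPDirective.STOP),
            ("negative", False, GPDirective.WITHHOLD),
        ],
    )
    def test_recent_screen_governs(self, result, on_vanco, expected):
        regimen = {"ceftriaxone"} | ({"vancomycin"} if on_vanco else set())
        assert apply_gp_rule([self.screen(result, 10)], regimen, as_of=T0) == expected

    def test_no_screen_gives_no_information(self):
        assert apply_gp_rule([], {"vancomycin"}, as_of=T0) == GPDirective.NO_INFORMATION

    def test_out_of_window_screen_ignored(self):
        d = apply_gp_rule([self.screen("positive", 120)], set(), as_of=T0, lookback_days=90)
        assert d == GPDirective.NO_INFORMATION

    def test_most_recent_screen_wins(self):
        screens = [self.screen("positive", 30), self.screen("negative", 5)]
        assert apply_gp_rule(screens, {"vancomycin"}, as_of=T0) == GPDirective.STOP


class TestRecommend:
    def models(self, **probs):
        base = dict(EXAMPLE_PROFILE)
        base.update(probs)
        return flat_model_set(base)

    def test_cap_uses_guideline_regimen(self):
        ep = make_episode(syndrome="community_acquired_pneumonia")
        rec = recommend(ep, self.models())
        assert rec.regimen == {"ceftriaxone", "azithromycin"}
        assert rec.arms == {"guideline"}

    def test_undifferentiated_uses_gn_arm(self):
        ep = make_episode(qsofa=1)
        rec = recommend(ep, self.models())
        assert rec.regimen == {"ceftriaxone"}
        assert rec.arms == {"gram_negative_model"}
        assert rec.threshold == 0.80

    def test_positive_mrsa_screen_adds_vancomycin(self):
        ep = make_episode(
            qsofa=1,
            mrsa_screens=[MRSAScreen(result="positive", collected=T0 - timedelta(days=10))],
        )
        rec = recommend(ep, self.models())
        assert rec.regimen == {"ceftriaxone", "vancomycin"}
        assert rec.arms == {"gram_negative_model", "gram_positive_rule"}

    def test_negative_screen_stops_current_vancomycin(self):
        ep = make_episode(
            current_regimen={"piperacillin-tazobactam", "vancomycin"},
            mrsa_screens=[MRSAScreen(result="negative", collected=T0 - timedelta(days=3))],
        )
        rec = recommend(ep, self.models())
        assert "vancomycin" not in rec.regimen

    def test_no_screen_retains_current_vancomycin(self):
        ep = make_episode(current_regimen={"ceftriaxone", "vancomycin"})
        rec = recommend(ep, self.models())
        assert "vancomycin" in rec.regimen
        assert rec.gp_directive == GPDirective.NO_INFORMATION

    def test_high_severity_uses_high_threshold(self):
        ep = make_episode(qsofa=3)
        rec = recommend(ep, self.models())
        assert rec.threshold == 0.90
        assert rec.regimen == {"piperacillin-tazobactam"}

    def test_gp_required_syndrome_walks_past_ciprofloxacin(self):
        ep = make_episode(syndrome="skin_soft_tissue_bone")
        rec = recommend(ep, self.models(ciprofloxacin=0.85))
        assert rec.regimen == {"ceftriaxone"}

    def test_anaerobic_syndrome_gets_metronidazole_adjunct(self):
        ep = make_episode(syndrome="intra_abdominal")
        rec = recommend(ep, self.models())
        assert rec.regimen == {"ceftriaxone", "metronidazole"}

    def test_guideline_vancomycin_survives_negative_screen(self):
        ep = make_episode(
            syndrome="cns_infection",
            mrsa_screens=[MRSAScreen(result="negative", collected=T0 - timedelta(days=3))],
        )
        rec = recommend(ep, self.models())
        assert "vancomycin" in rec.regimen  # guideline component, not MRSA-driven

    def test_unknown_syndrome_rejected_with_known_labels(self):
        ep = make_episode(syndrome="space_plague")
        with pytest.raises(ValidationError, match="space_plague"):
            recommend(ep, self.models())

    def test_shortfall_flagged_when_nothing_qualifies(self):
        ep = make_episode(qsofa=3)
        rec = recommend(ep, self.models(**{a: 0.5 for a in CASCADE}))
        assert rec.coverage_shortfall
        assert rec.regimen == {"meropenem"}

    def test_trace_records_every_arm_consulted(self):
        ep = make_episode(
            syndrome="community_acquired_pneumonia",
            mrsa_screens=[MRSAScreen(result="negative", collected=T0 - timedelta(days=3))],
        )
        rec = recommend(ep, self.models())
        text = " ".join(rec.trace)
        assert "guideline" in text and "gram-positive" in text
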