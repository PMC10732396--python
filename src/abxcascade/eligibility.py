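"""Inclusion/exclusion screening of suspected-sepsis episodes.

Inclusion: adult (>= 18 y), admitted to hospital, receiving an eligible
systemic antibiotic, with blood cultures ordered within +/- 12 hours of the
first antibiotic dose.  Exclusions: prior enrolment of the same patient,
palliative care, pregnancy, other inpatient antibiotic use in the prior
72 hours, and a positive clinical culture from the index event already
available at assessment.

Criteria are evaluated independently — the decision lists *every* violated
criterion, not just the first — and timestamps are compared at minute
resolution with inclusive window bounds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel

from .episode import PatientEpisode
from .errors import ValidationError
from .registry import AgentRegistry, default_registry

# criterion identifiers, reported in EligibilityDecision.failed_criteria
MINIMUM_AGE = "minimum_age"
ADMITTED = "admitted"
ELIGIBLE_ANTIBIOTIC = "eligible_antibiotic"
CULTURE_WINDOW = "culture_window"
PRIOR_EPISODE = "prior_episode"
PALLIATIVE_CARE = "palliative_care"
PREGNANCY = "pregnancy"
RECENT_ANTIBIOTICS = "recent_antibiotics"
PRIOR_POSITIVE_CULTURE = "prior_positive_culture"

ALL_CRITERIA = (
    MINIMUM_AGE,
    ADMITTED,
    ELIGIBLE_ANTIBIOTIC,
    CULTURE_WINDOW,
    PRIOR_EPISODE,
    PALLIATIVE_CARE,
    PREGNANCY,
    RECENT_ANTIBIOTICS,
    PRIOR_POSITIVE_CULTURE,
)


class EligibilityConfig(BaseModel):
    """Tunable screening parameters.

    ``eligible_antibiotics`` defaults to every agent the registry knows;
    the studied eligibility list is configurable because institutional
    formularies differ.
    """

    minimum_age: float = 18.0
    require_admission: bool = True
    culture_window_hours: float = 12.0
    recent_antibiotic_window_hours: float = 72.0
    eligible_antibiotics: Optional[list[str]] = None

    def eligible_set(self, registry: AgentRegistry) -> set[str]:
        if self.eligible_antibiotics is None:
            return registry.known_agents()
        return {registry.canonical(a) for a in self.eligible_antibiotics}


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    failed_criteria: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.eligible != (len(self.failed_criteria) == 0):
            raise ValidationError("eligible must equal 'no failed criteria'")


def _minutes_between(later: datetime, earlier: datetime) -> float:
    """Signed difference in whole minutes (timestamps truncated to minutes)."""
    a = later.replace(second=0, microsecond=0)
    b = earlier.replace(second=0, microsecond=0)
    return (a - b).total_seconds() / 60.0


def screen_episode(
    episode: PatientEpisode,
    config: Optional[EligibilityConfig] = None,
    registry: Optional[AgentRegistry] = None,
    *,
    prior_enrolled: Iterable[str] = (),
) -> EligibilityDecision:
    """Screen one episode against all inclusion and exclusion criteria.

    Parameters
    ----------
    prior_enrolled
        Patient ids already enrolled during earlier episodes; membership
        triggers the prior-episode exclusion.
    """
    config = config or EligibilityConfig()
    registry = registry or default_registry()

    if episode.age is None:
        raise ValidationError("missing mandatory field: age")
    if episode.admitted is None:
        raise ValidationError("missing mandatory field: admitted")
    if not episode.current_regimen:
        raise ValidationError(
            "missing mandatory field: current_regimen (antibiotic record)"
        )

    failed: set[str] = set()

    if episode.age < config.minimum_age:
        failed.add(MINIMUM_AGE)
    if config.require_admission and not episode.admitted:
        failed.add(ADMITTED)

    eligible_agents = config.eligible_set(registry)
    regimen = {registry.canonical(a) for a in episode.current_regimen}
    if not (regimen & eligible_agents):
        failed.add(ELIGIBLE_ANTIBIOTIC)

    ts = episode.timestamps
    if ts.blood_culture_order_time is None:
        failed.add(CULTURE_WINDOW)
    else:
        offset = _minutes_between(ts.blood_culture_order_time, ts.first_antibiotic_time)
        if abs(offset) > config.culture_window_hours * 60.0:
            failed.add(CULTURE_WINDOW)

    if episode.patient_id in set(prior_enrolled):
        failed.add(PRIOR_EPISODE)
    if episode.palliative_care:
        failed.add(PALLIATIVE_CARE)
    if episode.pregnant:
        failed.add(PREGNANCY)
    if episode.prior_antibiotic_time is not None:
        gap = _minutes_between(ts.first_antibiotic_time, episode.prior_antibiotic_time)
        if 0 < gap <= config.recent_antibiotic_window_hours * 60.0:
            failed.add(RECENT_ANTIBIOTICS)
    if episode.prior_positive_culture_available:
        failed.add(PRIOR_POSITIVE_CULTURE)

    return EligibilityDecision(eligible=not failed, failed_criteria=frozenset(failed))


def screen_cohort(
    episodes: Sequence[PatientEpisode],
    config: Optional[EligibilityConfig] = None,
    registry: Optional[AgentRegistry] = None,
) -> list[EligibilityDecision]:
    """Screen episodes in order, enrolling at most one episode per patient.

    The first eligible episode of a patient enrolls them; later episodes of
    the same patient fail the prior-episode exclusion.
    """
    enrolled: set[str] = set()
    decisions = []
    for ep in episodes:
        d = screen_episode(ep, config, registry, prior_enrolled=enrolled)
        if d.eligible:
            enrolled.add(ep.patient_id)
        decisions.append(d)
    return decisions
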