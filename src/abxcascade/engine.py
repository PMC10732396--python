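"""The treatment-recommendation engine.

Three arms combine into one recommended regimen:

1. **Guideline arm** — syndromes treated by a standard empiric regimen
   regardless of individual risk factors (cellulitis, community-acquired
   pneumonia, meningitis/CNS infection by default) get the local guideline
   regimen directly.
2. **Gram-negative model arm** — all other syndromes: predict per-agent
   susceptibility, then walk the spectrum cascade bottom-up and pick the
   narrowest agent whose predicted coverage meets the severity-dependent
   threshold (80% when qSOFA < 2, 90% when qSOFA >= 2 or on vasopressors).
   When the syndrome demands (non-MRSA) Gram-positive coverage that the
   chosen agent lacks, the walk continues up the cascade to the next agent
   with Gram-positive activity that still meets the threshold.
3. **Gram-positive rule** — vancomycin is added or stopped according to the
   most recent MRSA surveillance swab within the lookback window; with no
   in-window swab the patient's current vancomycin status is retained.

Every consulted arm is recorded in the recommendation's rationale trace.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .episode import MRSAScreen, PatientEpisode
from .errors import ConfigurationError, ValidationError
from .registry import AgentRegistry, VANCOMYCIN, default_registry
from .susceptibility import GNModelSet, PatientFeatures, coverage_profile


class SeverityThresholds(BaseModel):
    """Coverage thresholds by sepsis severity.

    ``qsofa_high_cutoff`` is the qSOFA score at or above which (or with any
    vasopressor support) the high threshold applies; the default of 2 follows
    the conventional qSOFA high-risk cut-point.
    """

    low: float = 0.80
    high: float = 0.90
    qsofa_high_cutoff: int = 2

    @model_validator(mode="after")
    def _ordered(self) -> "SeverityThresholds":
        if not (0.0 < self.low <= self.high < 1.0):
            raise ConfigurationError("thresholds must satisfy 0 < low <= high < 1")
        return self


def severity_threshold(
    qsofa: int, on_vasopressors: bool, thresholds: Optional[SeverityThresholds] = None
) -> float:
    """Coverage threshold for a patient: exactly ``low`` or ``high``."""
    thresholds = thresholds or SeverityThresholds()
    if qsofa not in (0, 1, 2, 3):
        raise ValidationError(f"qSOFA must be in 0..3, got {qsofa!r}")
    if on_vasopressors or qsofa >= thresholds.qsofa_high_cutoff:
        return thresholds.high
    return thresholds.low


class GPDirective(str, enum.Enum):
    """Vancomycin directive from the MRSA-screen rule."""

    ADD = "add"
    CONTINUE = "continue"
    STOP = "stop"
    WITHHOLD = "withhold"
    NO_INFORMATION = "no_information"

    @property
    def informative(self) -> bool:
        return self is not GPDirective.NO_INFORMATION

    @property
    def wants_vancomycin(self) -> bool:
        return self in (GPDirective.ADD, GPDirective.CONTINUE)


def apply_gp_rule(
    mrsa_screens: Sequence[MRSAScreen],
    current_regimen: set[str],
    *,
    lookback_days: float = 90.0,
    as_of: Optional[datetime] = None,
    registry: Optional[AgentRegistry] = None,
) -> GPDirective:
    """Vancomycin directive from the most recent in-window MRSA screen.

    Positive -> add (if absent) / continue (if present); negative -> stop
    (if present) / withhold (if absent); no in-window screen ->
    ``NO_INFORMATION`` (current vancomycin status is retained, since absent
    surveillance data cannot justify stopping empiric MRSA coverage).
    """
    registry = registry or default_registry()
    on_vanco = any(
        registry.canonical(a) in registry.gp_agents for a in current_regimen
    )
    in_window = list(mrsa_screens)
    if as_of is not None:
        cutoff = as_of - timedelta(days=lookback_days)
        in_window = [s for s in in_window if cutoff <= s.collected <= as_of]
    if not in_window:
        return GPDirective.NO_INFORMATION
    latest = max(in_window, key=lambda s: s.collected)
    if latest.result == "positive":
        return GPDirective.CONTINUE if on_vanco else GPDirective.ADD
    return GPDirective.STOP if on_vanco else GPDirective.WITHHOLD


@dataclass(frozen=True)
class CascadeSelection:
    """Outcome of one walk up the cascade."""

    agent: str
    shortfall: bool = False  # no agent met the threshold; broadest returned
    gp_adjusted: bool = False  # moved up to obtain Gram-positive coverage


def walk_cascade(
    profile: Mapping[str, float],
    threshold: float,
    gp_required: bool,
    registry: Optional[AgentRegistry] = None,
    *,
    strict: bool = False,
) -> CascadeSelection:
    """Narrowest cascade agent whose predicted coverage meets ``threshold``.

    With ``gp_required`` and a first choice lacking Gram-positive coverage,
    the walk moves further up the cascade to the narrowest qualifying agent
    that provides it.  When nothing qualifies the broadest agent is returned
    with ``shortfall=True``.  ``strict`` switches the comparison from >= to >.
    """
    registry = registry or default_registry()
    if not registry.cascade:
        raise ConfigurationError("cascade is empty")
    missing = [a for a in registry.cascade if a not in profile]
    if missing:
        raise ConfigurationError(f"coverage profile missing cascade agents: {missing}")

    def meets(agent: str) -> bool:
        p = profile[agent]
        return p > threshold if strict else p >= threshold

    qualifying = [a for a in registry.cascade if meets(a)]
    if not qualifying:
        # fall back to the broadest (GP-covering, if demanded) agent
        pool = registry.cascade
        if gp_required:
            gp_pool = [a for a in pool if registry.has_gp_coverage(a)]
            pool = gp_pool or pool
        return CascadeSelection(agent=pool[-1], shortfall=True, gp_adjusted=gp_required)

    first = qualifying[0]
    if not gp_required or registry.has_gp_coverage(first):
        return CascadeSelection(agent=first)

    start = registry.position(first)
    for agent in qualifying:
        if registry.position(agent) >= start and registry.has_gp_coverage(agent):
            return CascadeSelection(agent=agent, gp_adjusted=True)
    # threshold is met somewhere, but never together with GP coverage
    gp_pool = [a for a in registry.cascade if registry.has_gp_coverage(a)]
    fallback = gp_pool[-1] if gp_pool else registry.broadest
    return CascadeSelection(agent=fallback, shortfall=True, gp_adjusted=True)


class EngineConfig(BaseModel):
    """Declarative configuration of the recommendation engine."""

    thresholds: SeverityThresholds = Field(default_factory=SeverityThresholds)
    #: syndrome -> standard empiric regimen (local guideline)
    guidelines: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "cellulitis": ["cefazolin"],
            "community_acquired_pneumonia": ["ceftriaxone", "azithromycin"],
            "meningitis": ["ceftriaxone", "vancomycin"],
            "cns_infection": ["ceftriaxone", "vancomycin"],
        }
    )
    #: syndromes demanding non-MRSA Gram-positive coverage from the GN arm
    gp_required_syndromes: list[str] = Field(
        default_factory=lambda: ["skin_soft_tissue_bone", "odontogenic"]
    )
    #: syndromes that get an anaerobic adjunct when the chosen agent lacks it
    anaerobic_syndromes: list[str] = Field(
        default_factory=lambda: ["intra_abdominal", "hepatobiliary", "odontogenic"]
    )
    #: syndromes the engine recognizes but routes through the GN model arm
    known_syndromes: list[str] = Field(
        default_factory=lambda: [
            "undifferentiated",
            "unknown",
            "other",
            "pneumonia",
            "uti",
            "febrile_neutropenia",
            "intra_abdominal",
            "hepatobiliary",
            "skin_soft_tissue_bone",
            "odontogenic",
        ]
    )
    mrsa_lookback_days: float = 90.0
    strict_threshold: bool = False
    anaerobic_adjunct: str = "metronidazole"

    def all_syndromes(self) -> set[str]:
        return set(self.guidelines) | set(self.known_syndromes)


# arm labels recorded on recommendations
ARM_GUIDELINE = "guideline"
ARM_GN_MODEL = "gram_negative_model"
ARM_GP_RULE = "gram_positive_rule"


@dataclass
class Recommendation:
    """Recommended regimen with full decision rationale."""

    episode_id: str
    regimen: set[str]
    arms: set[str]
    threshold: Optional[float] = None
    profile: Optional[dict[str, float]] = None
    gp_directive: GPDirective = GPDirective.NO_INFORMATION
    coverage_shortfall: bool = False
    trace: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.regimen:
            raise ValidationError("recommended regimen must be non-empty")


def recommend(
    episode: PatientEpisode,
    models: GNModelSet,
    registry: Optional[AgentRegistry] = None,
    config: Optional[EngineConfig] = None,
) -> Recommendation:
    """Full recommendation for one eligible episode."""
    registry = registry or default_registry()
    config = config or EngineConfig()
    syndrome = episode.syndrome
    known = config.all_syndromes()
    if syndrome not in known:
        raise ValidationError(
            f"unknown syndrome {syndrome!r}; known labels: {sorted(known)}"
        )

    trace: list[str] = []
    arms: set[str] = set()
    threshold: Optional[float] = None
    profile: Optional[dict[str, float]] = None
    shortfall = False
    guideline_regimen: Optional[set[str]] = None

    if syndrome in config.guidelines:
        guideline_regimen = {registry.canonical(a) for a in config.guidelines[syndrome]}
        regimen = set(guideline_regimen)
        arms.add(ARM_GUIDELINE)
        trace.append(
            f"guideline arm: syndrome {syndrome!r} -> {sorted(guideline_regimen)}"
        )
    else:
        features = PatientFeatures.from_episode(episode, registry)
        profile = coverage_profile(features, models, registry)
        threshold = severity_threshold(
            episode.qsofa, episode.on_vasopressors, config.thresholds
        )
        gp_required = syndrome in set(config.gp_required_syndromes)
        selection = walk_cascade(
            profile, threshold, gp_required, registry, strict=config.strict_threshold
        )
        shortfall = selection.shortfall
        regimen = {selection.agent}
        arms.add(ARM_GN_MODEL)
        trace.append(
            f"gram-negative arm: threshold {threshold:.2f}"
            f" (qSOFA {episode.qsofa}, vasopressors {episode.on_vasopressors});"
            f" profile {{{', '.join(f'{a}: {p:.3f}' for a, p in profile.items())}}}"
            f" -> {selection.agent}"
        )
        if selection.gp_adjusted:
            trace.append(
                "gram-negative arm: moved up the cascade for Gram-positive coverage"
            )
        if selection.shortfall:
            trace.append(
                "gram-negative arm: no agent met the coverage threshold;"
                " broadest agent recommended (predicted-coverage shortfall)"
            )
        if syndrome in set(config.anaerobic_syndromes) and not (
            regimen & set(registry.anaerobic_coverage)
        ):
            regimen.add(registry.canonical(config.anaerobic_adjunct))
            trace.append(
                f"adjunct rule: added {config.anaerobic_adjunct} for anaerobic"
                f" coverage in {syndrome!r}"
            )

    directive = apply_gp_rule(
        episode.mrsa_screens,
        episode.current_regimen,
        lookback_days=config.mrsa_lookback_days,
        as_of=episode.timestamps.assessment_time,
        registry=registry,
    )
    if directive.informative:
        arms.add(ARM_GP_RULE)
    vanco = registry.canonical(VANCOMYCIN)
    guideline_vanco = guideline_regimen is not None and vanco in guideline_regimen
    currently_on_vanco = any(
        registry.canonical(a) in registry.gp_agents for a in episode.current_regimen
    )
    if directive.wants_vancomycin:
        regimen.add(vanco)
        trace.append(f"gram-positive rule: MRSA screen positive -> {directive.value} vancomycin")
    elif directive is GPDirective.STOP:
        if guideline_vanco:
            trace.append(
                "gram-positive rule: negative MRSA screen, but vancomycin is part"
                " of the guideline regimen and is retained"
            )
        else:
            regimen.discard(vanco)
            trace.append("gram-positive rule: MRSA screen negative -> stop vancomycin")
    elif directive is GPDirective.WITHHOLD:
        trace.append("gram-positive rule: MRSA screen negative -> withhold vancomycin")
    else:
        if currently_on_vanco and not guideline_vanco:
            regimen.add(vanco)
        trace.append(
            "gram-positive rule: no MRSA screen in window -> current vancomycin"
            " status retained"
        )

    return Recommendation(
        episode_id=episode.episode_id,
        regimen=regimen,
        arms=arms,
        threshold=threshold,
        profile=profile,
        gp_directive=directive,
        coverage_shortfall=shortfall,
        trace=trace,
    )
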