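"""Received-vs-recommended spectrum classification.

De-escalation = movement down the Gram-negative cascade or cessation of
vancomycin/daptomycin; escalation = movement up the cascade or addition of
vancomycin/daptomycin; otherwise no change.  Adjuncts (azithromycin,
metronidazole) never change the spectrum level, and the defined equivalence
classes (ertapenem~meropenem, gentamicin~ceftazidime, levofloxacin~CAP
guideline level) collapse to zero steps.

Mixed-direction changes (cascade down but vancomycin added, or vice versa)
are assigned one category by a configurable precedence; the default treats
any broadening as an escalation.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import ValidationError
from .registry import AgentRegistry, default_registry


class Direction(str, enum.Enum):
    DE_ESCALATION = "de_escalation"
    ESCALATION = "escalation"
    NO_CHANGE = "no_change"


class GPChange(str, enum.Enum):
    ADDED = "added"
    STOPPED = "stopped"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class NormalizedRegimen:
    """A regimen reduced to its spectrum coordinates.

    ``gn_level`` is the maximum cascade position present (0 when only
    narrow-tier agents, or no Gram-negative-active agent at all, are given);
    ``gp_active`` flags vancomycin/daptomycin; adjuncts are recorded but do
    not contribute to the level.
    """

    gn_level: int
    gn_agents: frozenset[str]
    gp_active: bool
    adjuncts: frozenset[str]
    below_cascade: bool


def normalize_regimen(
    regimen: Iterable[str],
    registry: Optional[AgentRegistry] = None,
    syndrome: Optional[str] = None,
) -> NormalizedRegimen:
    """Map a regimen onto the cascade axis, GP axis and adjunct set."""
    registry = registry or default_registry()
    levels: list[int] = []
    gn_agents: set[str] = set()
    adjuncts: set[str] = set()
    gp_active = False
    below = False
    for name in regimen:
        agent = registry.canonical(name)  # raises UnknownAgentError
        if agent in registry.gp_agents:
            gp_active = True
            continue
        if agent in registry.adjuncts:
            adjuncts.add(agent)
            continue
        level = registry.spectrum_level(agent, syndrome=syndrome)
        assert level is not None
        levels.append(level)
        gn_agents.add(agent)
        if level == 0:
            below = True
    return NormalizedRegimen(
        gn_level=max(levels) if levels else 0,
        gn_agents=frozenset(gn_agents),
        gp_active=gp_active,
        adjuncts=frozenset(adjuncts),
        below_cascade=below and max(levels) == 0,
    )


@dataclass(frozen=True)
class SpectrumChange:
    """Direction and magnitude of a received -> recommended regimen change."""

    direction: Direction
    gn_steps: int
    gp_change: GPChange
    total_steps: int
    gn_direction: Direction  # cascade axis alone

    def __post_init__(self):
        if self.direction is Direction.NO_CHANGE and self.total_steps != 0:
            raise ValidationError("no_change implies zero total steps")


def classify_change(
    received: Iterable[str],
    recommended: Iterable[str],
    registry: Optional[AgentRegistry] = None,
    syndrome: Optional[str] = None,
    *,
    escalation_precedence: bool = True,
) -> SpectrumChange:
    """Classify the recommended regimen relative to the received one.

    ``gn_steps`` is the absolute cascade-position difference of the
    normalized levels; a vancomycin/daptomycin add or stop contributes one
    further step to ``total_steps``.
    """
    registry = registry or default_registry()
    received = list(received)
    if not received:
        raise ValidationError("received regimen must be non-empty")
    recv = normalize_regimen(received, registry, syndrome)
    reco = normalize_regimen(recommended, registry, syndrome)

    delta = reco.gn_level - recv.gn_level
    gn_steps = abs(delta)
    if delta > 0:
        gn_direction = Direction.ESCALATION
    elif delta < 0:
        gn_direction = Direction.DE_ESCALATION
    else:
        gn_direction = Direction.NO_CHANGE

    if reco.gp_active and not recv.gp_active:
        gp_change = GPChange.ADDED
    elif recv.gp_active and not reco.gp_active:
        gp_change = GPChange.STOPPED
    else:
        gp_change = GPChange.UNCHANGED

    up = delta > 0 or gp_change is GPChange.ADDED
    down = delta < 0 or gp_change is GPChange.STOPPED
    if up and down:
        direction = (
            Direction.ESCALATION if escalation_precedence else Direction.DE_ESCALATION
        )
    elif up:
        direction = Direction.ESCALATION
    elif down:
        direction = Direction.DE_ESCALATION
    else:
        direction = Direction.NO_CHANGE

    total = gn_steps + (1 if gp_change is not GPChange.UNCHANGED else 0)
    return SpectrumChange(
        direction=direction,
        gn_steps=gn_steps,
        gp_change=gp_change,
        total_steps=total,
        gn_direction=gn_direction,
    )
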