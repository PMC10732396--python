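"""Antibiotic agent registry and the a-priori Gram-negative spectrum cascade.

The decision algorithm ranks the commonly used Gram-negative agents on a
single ordinal "spectrum cascade", narrowest to broadest::

    ciprofloxacin < ceftriaxone < ceftazidime < piperacillin-tazobactam < meropenem

Every other agent the tool understands is mapped onto this axis in one of
four ways:

* **equivalent** — identical spectrum level to a cascade agent
  (ertapenem ~ meropenem, gentamicin ~ ceftazidime);
* **narrow tier** — narrow-spectrum agents below the cascade
  (cefazolin, ampicillin, cephalexin, clindamycin, doxycycline), treated as
  spectrum level 0, one step below ciprofloxacin;
* **adjunct** — atypical/anaerobic add-ons that do not change spectrum level
  (azithromycin, metronidazole);
* **Gram-positive axis** — vancomycin and daptomycin, tracked separately
  from the Gram-negative cascade.

Levofloxacin is context dependent: under the community-acquired-pneumonia
guideline it is spectrum-equivalent to ceftriaxone + azithromycin; otherwise
it sits at ciprofloxacin's level (same drug class).
"""
from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, UnknownAgentError

# Canonical agent names used throughout the package.
CIPROFLOXACIN = "ciprofloxacin"
CEFTRIAXONE = "ceftriaxone"
CEFTAZIDIME = "ceftazidime"
PIPERACILLIN_TAZOBACTAM = "piperacillin-tazobactam"
MEROPENEM = "meropenem"
VANCOMYCIN = "vancomycin"
DAPTOMYCIN = "daptomycin"

DEFAULT_CASCADE = (
    CIPROFLOXACIN,
    CEFTRIAXONE,
    CEFTAZIDIME,
    PIPERACILLIN_TAZOBACTAM,
    MEROPENEM,
)


class AgentRegistry(BaseModel):
    """Registry of antibiotic agents and their place on the spectrum cascade.

    Parameters mirror the declarative YAML/JSON configuration; the defaults
    encode the study cascade and equivalence classes described above.
    """

    cascade: list[str] = Field(default_factory=lambda: list(DEFAULT_CASCADE))
    gram_positive_coverage: dict[str, bool] = Field(
        default_factory=lambda: {
            CIPROFLOXACIN: False,
            CEFTRIAXONE: True,
            CEFTAZIDIME: False,
            PIPERACILLIN_TAZOBACTAM: True,
            MEROPENEM: True,
        }
    )
    #: non-cascade agent -> cascade agent with the same spectrum level
    equivalences: dict[str, str] = Field(
        default_factory=lambda: {
            "ertapenem": MEROPENEM,
            "gentamicin": CEFTAZIDIME,
        }
    )
    #: narrow-spectrum agents below the cascade (spectrum level 0)
    narrow_tier: list[str] = Field(
        default_factory=lambda: [
            "cefazolin",
            "ampicillin",
            "cephalexin",
            "clindamycin",
            "doxycycline",
        ]
    )
    #: atypical / anaerobic adjuncts, excluded from the spectrum level
    adjuncts: list[str] = Field(default_factory=lambda: ["azithromycin", "metronidazole"])
    #: MRSA-level Gram-positive agents tracked on their own axis
    gp_agents: list[str] = Field(default_factory=lambda: [VANCOMYCIN, DAPTOMYCIN])
    #: agents with reliable anaerobic activity (used by the adjunct rule)
    anaerobic_coverage: list[str] = Field(
        default_factory=lambda: [PIPERACILLIN_TAZOBACTAM, MEROPENEM, "ertapenem"]
    )
    #: name aliases, matched case-insensitively
    aliases: dict[str, str] = Field(
        default_factory=lambda: {
            "pip-tazo": PIPERACILLIN_TAZOBACTAM,
            "piperacillin/tazobactam": PIPERACILLIN_TAZOBACTAM,
            "tazocin": PIPERACILLIN_TAZOBACTAM,
            "cipro": CIPROFLOXACIN,
        }
    )
    #: fluoroquinolone whose level depends on the syndrome context
    levofloxacin: str = "levofloxacin"

    @model_validator(mode="after")
    def _check(self) -> "AgentRegistry":
        if not self.cascade:
            raise ConfigurationError("cascade must contain at least one agent")
        if len(set(self.cascade)) != len(self.cascade):
            raise ConfigurationError("cascade agents must be unique")
        missing = [a for a in self.cascade if a not in self.gram_positive_coverage]
        if missing:
            raise ConfigurationError(
                f"gram_positive_coverage missing for cascade agents: {missing}"
            )
        bad = [a for a, tgt in self.equivalences.items() if tgt not in self.cascade]
        if bad:
            raise ConfigurationError(f"equivalences must map onto cascade agents: {bad}")
        return self

    # ----- lookups ---------------------------------------------------

    def canonical(self, name: str) -> str:
        """Resolve an agent name (case-insensitive, alias-aware) or raise."""
        key = name.strip().lower()
        key = self.aliases.get(key, key)
        if key in self.known_agents():
            return key
        raise UnknownAgentError(name)

    def known_agents(self) -> set[str]:
        return (
            set(self.cascade)
            | set(self.equivalences)
            | set(self.narrow_tier)
            | set(self.adjuncts)
            | set(self.gp_agents)
            | {self.levofloxacin}
        )

    def position(self, agent: str) -> int:
        """1-based cascade position; equivalents map to their class; 0 = narrow tier."""
        agent = self.canonical(agent)
        if agent in self.equivalences:
            agent = self.equivalences[agent]
        if agent in self.cascade:
            return self.cascade.index(agent) + 1
        if agent in self.narrow_tier:
            return 0
        raise ConfigurationError(f"agent {agent!r} has no cascade position")

    def has_gp_coverage(self, agent: str) -> bool:
        return self.gram_positive_coverage.get(self.canonical(agent), False)

    def spectrum_level(self, agent: str, syndrome: Optional[str] = None) -> Optional[int]:
        """Gram-negative spectrum level of a single agent, or None for
        adjuncts and Gram-positive-axis agents (which carry no GN level)."""
        agent = self.canonical(agent)
        if agent in self.adjuncts or agent in self.gp_agents:
            return None
        if agent == self.levofloxacin:
            if syndrome is not None and _is_cap(syndrome):
                return self.position(CEFTRIAXONE)
            return self.position(CIPROFLOXACIN)
        return self.position(agent)

    @property
    def broadest(self) -> str:
        return self.cascade[-1]

    @property
    def narrowest(self) -> str:
        return self.cascade[0]


def _is_cap(syndrome: str) -> bool:
    s = syndrome.strip().lower()
    return s in {"community_acquired_pneumonia", "cap"}


def default_registry() -> AgentRegistry:
    """The study cascade with default equivalence classes and flags."""
    return AgentRegistry()
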