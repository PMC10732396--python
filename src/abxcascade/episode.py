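"""Core domain records: suspected-sepsis episodes and culture results."""
from __future__ import annotations

from datetime import datetime
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ValidationError

ScreenResult = Literal["positive", "negative"]
PanelResult = Literal["susceptible", "resistant", "not_tested"]


class MRSAScreen(BaseModel):
    """One MRSA surveillance swab result."""

    result: ScreenResult
    collected: datetime


class EpisodeTimestamps(BaseModel):
    """Timing anchors for an episode.

    ``blood_culture_order_time`` may be absent (no culture ordered), which
    fails the culture-window inclusion criterion downstream rather than
    raising here.
    """

    first_antibiotic_time: datetime
    blood_culture_order_time: Optional[datetime] = None
    assessment_time: datetime

    @model_validator(mode="after")
    def _ordering(self) -> "EpisodeTimestamps":
        if self.assessment_time < self.first_antibiotic_time:
            raise ValueError("assessment_time must not precede first_antibiotic_time")
        return self


class PatientEpisode(BaseModel):
    """One suspected-sepsis episode: demographics, exposures, severity,
    syndrome and the empiric regimen in place at assessment.

    ``prior_resistant_organisms_1y`` holds the set of antibiotics to which a
    clinical isolate from the preceding year was resistant.
    """

    episode_id: str
    patient_id: str
    age: float = Field(ge=0, le=120)
    female: bool
    admitted: bool
    hospital_acquired: bool = False
    prior_hospitalization_90d: bool = False
    prior_icu_90d: bool = False
    prior_antibiotic_exposure_90d: bool = False
    prior_resistant_organisms_1y: set[str] = Field(default_factory=set)
    qsofa: int = Field(ge=0, le=3)
    on_vasopressors: bool = False
    on_mechanical_ventilation: bool = False
    neutropenic: bool = False
    syndrome: str = "undifferentiated"
    current_regimen: set[str] = Field(default_factory=set)
    timestamps: EpisodeTimestamps
    mrsa_screens: list[MRSAScreen] = Field(default_factory=list)
    # exclusion-relevant history; absent flags default to False (observational
    # screening behaviour — the screen assumes no exclusion unless documented)
    prior_antibiotic_time: Optional[datetime] = None
    palliative_care: bool = False
    pregnant: bool = False
    prior_positive_culture_available: bool = False

    @field_validator("syndrome")
    @classmethod
    def _norm_syndrome(cls, v: str) -> str:
        return v.strip().lower()


class CultureResult(BaseModel):
    """One clinical isolate with its susceptibility panel.

    ``clinically_relevant`` is supplied by the chart reviewer (or generator),
    never inferred: contaminants and colonizers are excluded from adequacy
    denominators through this flag.
    """

    episode_id: str
    specimen: Literal["blood", "non_blood"]
    organism: str = "unspecified"
    clinically_relevant: bool = True
    panel: dict[str, PanelResult] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _panel_nonempty(self) -> "CultureResult":
        if self.clinically_relevant and not self.panel:
            raise ValidationError(
                f"clinically relevant isolate for episode {self.episode_id} "
                "must carry a non-empty susceptibility panel"
            )
        return self
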