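"""Readers and writers for the package's tabular and JSON artifacts.

Episode and culture tables are plain CSV; set-valued columns use
semicolon-separated lists and MRSA screens are encoded as
``ISO-date=result`` pairs.  Timestamps are ISO-8601.  Errors name the
offending row and field.
"""
from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .episode import CultureResult, EpisodeTimestamps, MRSAScreen, PatientEpisode
from .errors import ValidationError

EPISODE_COLUMNS = [
    "episode_id",
    "patient_id",
    "age",
    "female",
    "admitted",
    "hospital_acquired",
    "prior_hospitalization_90d",
    "prior_icu_90d",
    "prior_antibiotic_exposure_90d",
    "prior_resistant_organisms_1y",
    "qsofa",
    "on_vasopressors",
    "on_mechanical_ventilation",
    "neutropenic",
    "syndrome",
    "current_regimen",
    "first_antibiotic_time",
    "blood_culture_order_time",
    "assessment_time",
    "mrsa_screens",
    "prior_antibiotic_time",
    "palliative_care",
    "pregnant",
    "prior_positive_culture_available",
]

CULTURE_COLUMNS = ["episode_id", "specimen", "organism", "clinically_relevant", "panel"]

_SET_SEP = ";"
_KV_SEP = "="


def _fmt_ts(ts: Optional[datetime]) -> str:
    return "" if ts is None else ts.isoformat()


def _parse_ts(value, row: int, field: str) -> Optional[datetime]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return datetime.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparseable timestamp in {field!r}: {value!r}") from exc


def _parse_bool(value, row: int, field: str) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"row {row}: unparseable boolean in {field!r}: {value!r}")


def _split_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return set()
    return {p for p in str(value).split(_SET_SEP) if p}


def episodes_to_frame(episodes: list[PatientEpisode]) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        rows.append(
            {
                "episode_id": ep.episode_id,
                "patient_id": ep.patient_id,
                "age": ep.age,
                "female": ep.female,
                "admitted": ep.admitted,
                "hospital_acquired": ep.hospital_acquired,
                "prior_hospitalization_90d": ep.prior_hospitalization_90d,
                "prior_icu_90d": ep.prior_icu_90d,
                "prior_antibiotic_exposure_90d": ep.prior_antibiotic_exposure_90d,
                "prior_resistant_organisms_1y": _SET_SEP.join(
                    sorted(ep.prior_resistant_organisms_1y)
                ),
                "qsofa": ep.qsofa,
                "on_vasopressors": ep.on_vasopressors,
                "on_mechanical_ventilation": ep.on_mechanical_ventilation,
                "neutropenic": ep.neutropenic,
                "syndrome": ep.syndrome,
                "current_regimen": _SET_SEP.join(sorted(ep.current_regimen)),
                "first_antibiotic_time": _fmt_ts(ep.timestamps.first_antibiotic_time),
                "blood_culture_order_time": _fmt_ts(ep.timestamps.blood_culture_order_time),
                "assessment_time": _fmt_ts(ep.timestamps.assessment_time),
                "mrsa_screens": _SET_SEP.join(
                    f"{s.collected.isoformat()}{_KV_SEP}{s.result}" for s in ep.mrsa_screens
                ),
                "prior_antibiotic_time": _fmt_ts(ep.prior_antibiotic_time),
                "palliative_care": ep.palliative_care,
                "pregnant": ep.pregnant,
                "prior_positive_culture_available": ep.prior_positive_culture_available,
            }
        )
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def write_episodes(episodes: list[PatientEpisode], path: str | Path) -> None:
    episodes_to_frame(episodes).to_csv(path, index=False)


def read_episodes(path: str | Path) -> list[PatientEpisode]:
    """Read an episode CSV (or JSON list) into typed episodes."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EPISODE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"episode table missing columns: {missing}")

    episodes = []
    for i, rec in enumerate(frame.to_dict("records")):
        try:
            screens = []
            for token in _split_set(rec["mrsa_screens"]):
                when, _, result = token.partition(_KV_SEP)
                screens.append(
                    MRSAScreen(result=result, collected=_parse_ts(when, i, "mrsa_screens"))
                )
            episodes.append(
                PatientEpisode(
                    episode_id=str(rec["episode_id"]),
                    patient_id=str(rec["patient_id"]),
                    age=float(rec["age"]),
                    female=_parse_bool(rec["female"], i, "female"),
                    admitted=_parse_bool(rec["admitted"], i, "admitted"),
                    hospital_acquired=_parse_bool(rec["hospital_acquired"], i, "hospital_acquired"),
                    prior_hospitalization_90d=_parse_bool(
                        rec["prior_hospitalization_90d"], i, "prior_hospitalization_90d"
                    ),
                    prior_icu_90d=_parse_bool(rec["prior_icu_90d"], i, "prior_icu_90d"),
                    prior_antibiotic_exposure_90d=_parse_bool(
                        rec["prior_antibiotic_exposure_90d"], i, "prior_antibiotic_exposure_90d"
                    ),
                    prior_resistant_organisms_1y=_split_set(rec["prior_resistant_organisms_1y"]),
                    qsofa=int(rec["qsofa"]),
                    on_vasopressors=_parse_bool(rec["on_vasopressors"], i, "on_vasopressors"),
                    on_mechanical_ventilation=_parse_bool(
                        rec["on_mechanical_ventilation"], i, "on_mechanical_ventilation"
                    ),
                    neutropenic=_parse_bool(rec["neutropenic"], i, "neutropenic"),
                    syndrome=str(rec["syndrome"]),
                    current_regimen=_split_set(rec["current_regimen"]),
                    timestamps=EpisodeTimestamps(
                        first_antibiotic_time=_parse_ts(
                            rec["first_antibiotic_time"], i, "first_antibiotic_time"
                        ),
                        blood_culture_order_time=_parse_ts(
                            rec["blood_culture_order_time"], i, "blood_culture_order_time"
                        ),
                        assessment_time=_parse_ts(rec["assessment_time"], i, "assessment_time"),
                    ),
                    mrsa_screens=screens,
                    prior_antibiotic_time=_parse_ts(
                        rec["prior_antibiotic_time"], i, "prior_antibiotic_time"
                    ),
                    palliative_care=_parse_bool(rec["palliative_care"], i, "palliative_care"),
                    pregnant=_parse_bool(rec["pregnant"], i, "pregnant"),
                    prior_positive_culture_available=_parse_bool(
                        rec["prior_positive_culture_available"],
                        i,
                        "prior_positive_culture_available",
                    ),
                )
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return episodes


def cultures_to_frame(cultures: list[CultureResult]) -> pd.DataFrame:
    rows = [
        {
            "episode_id": c.episode_id,
            "specimen": c.specimen,
            "organism": c.organism,
            "clinically_relevant": c.clinically_relevant,
            "panel": _SET_SEP.join(f"{a}{_KV_SEP}{r}" for a, r in sorted(c.panel.items())),
        }
        for c in cultures
    ]
    return pd.DataFrame(rows, columns=CULTURE_COLUMNS)


def write_cultures(cultures: list[CultureResult], path: str | Path) -> None:
    cultures_to_frame(cultures).to_csv(path, index=False)


def read_cultures(path: str | Path) -> list[CultureResult]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CULTURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"culture table missing columns: {missing}")
    out = []
    for i, rec in enumerate(frame.to_dict("records")):
        panel = {}
        for token in _split_set(rec["panel"]):
            agent, _, result = token.partition(_KV_SEP)
            if result not in {"susceptible", "resistant", "not_tested"}:
                raise ValidationError(f"row {i}: bad panel result {result!r} in 'panel'")
            panel[agent] = result
        out.append(
            CultureResult(
                episode_id=str(rec["episode_id"]),
                specimen=str(rec["specimen"]),
                organism=str(rec["organism"]),
                clinically_relevant=_parse_bool(
                    rec["clinically_relevant"], i, "clinically_relevant"
                ),
                panel=panel,
            )
        )
    return out


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return data
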