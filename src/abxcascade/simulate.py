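"""Synthetic suspected-sepsis cohort generator.

Emulates the statistical structure the decision algorithm assumes: marginal
demographics and exposure prevalences of a tertiary-care early-sepsis
cohort, a syndrome mix, clinician empiric regimens drawn from observed
prescribing frequencies, and — crucially — a *known* ground-truth logistic
susceptibility model linking each patient's history to the latent
susceptibility of their (potential) pathogen, so that model fitting,
calibration and the full pipeline can be validated against truth.

All randomness flows from one seeded NumPy generator; draws happen
column-by-column in the fixed order laid out in :func:`generate_cohort`, so
cohorts are bit-reproducible for a given (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .episode import CultureResult, EpisodeTimestamps, MRSAScreen, PatientEpisode
from .errors import ValidationError
from .registry import DEFAULT_CASCADE, default_registry
from .susceptibility import AGE_CENTER, FEATURE_NAMES, AgentModel, GNModelSet


def default_ground_truth() -> dict[str, dict[str, float]]:
    """Ground-truth log-odds models per cascade agent.

    Intercepts put the baseline (65-year-old male, no risk history)
    susceptibility near typical Gram-negative antibiogram rates — rising
    along the cascade from ~0.80 (ciprofloxacin) to ~0.97 (meropenem) — and
    the history coefficients encode the usual direction of effect: prior
    same-agent resistance is strongly unfavourable, recent healthcare and
    antibiotic exposure moderately so.
    """
    shared = {
        "age_centered": -0.01,
        "female": 0.10,
        "prior_hospitalization_90d": -0.50,
        "prior_icu_90d": -0.60,
        "prior_antibiotic_exposure_90d": -0.70,
        "prior_resistance_same_agent_1y": -2.20,
    }
    intercepts = {
        "ciprofloxacin": 1.386,  # expit -> 0.800
        "ceftriaxone": 1.658,  # 0.840
        "ceftazidime": 1.992,  # 0.880
        "piperacillin-tazobactam": 2.442,  # 0.920
        "meropenem": 3.476,  # 0.970
    }
    return {
        agent: {"intercept": b0, **shared} for agent, b0 in intercepts.items()
    }


def ground_truth_model_set(
    ground_truth: Optional[dict[str, dict[str, float]]] = None,
) -> GNModelSet:
    """Wrap ground-truth coefficients as a GNModelSet (non-clinical: these
    are simulation constants, not institutionally calibrated models)."""
    gt = ground_truth or default_ground_truth()
    models = {
        agent: AgentModel(
            agent=agent,
            intercept=coefs["intercept"],
            coefficients={f: coefs[f] for f in FEATURE_NAMES},
            n=None,
            converged=True,
        )
        for agent, coefs in gt.items()
    }
    return GNModelSet(models=models)


def _default_syndromes() -> dict[str, float]:
    # cohort syndrome mix; skin/soft-tissue 14% split into a cellulitis
    # (guideline) share consistent with observed cefazolin recommendations
    return {
        "cns_infection": 0.019,
        "febrile_neutropenia": 0.121,
        "hepatobiliary": 0.037,
        "intra_abdominal": 0.065,
        "odontogenic": 0.019,
        "pneumonia": 0.224,
        "cellulitis": 0.075,
        "skin_soft_tissue_bone": 0.065,
        "undifferentiated": 0.244,
        "uti": 0.131,
    }


def _default_regimen_freq() -> dict[str, float]:
    # observed primary-agent prescribing counts (non-adjunct agents)
    return {
        "ampicillin": 1,
        "ciprofloxacin": 1,
        "cefazolin": 10,
        "ceftazidime": 1,
        "ceftriaxone": 34,
        "cephalexin": 1,
        "clindamycin": 1,
        "doxycycline": 2,
        "ertapenem": 2,
        "gentamicin": 1,
        "levofloxacin": 1,
        "meropenem": 5,
        "piperacillin-tazobactam": 52,
    }


class CohortSpec(BaseModel):
    """Generator configuration; defaults mirror the emulated cohort's
    marginal structure (demographics, exposures, severity, syndromes,
    prescribing) and observed culture and MRSA-screen rates."""

    n: int = Field(default=107, ge=1)
    seed: int = 0

    age_mean: float = 66.3
    age_sd: float = 19.7
    female: float = 0.393
    hospital_acquired: float = 0.252
    prior_hospitalization_90d: float = 0.318
    prior_icu_90d: float = 0.084
    prior_antibiotic_exposure_90d: float = 0.25
    qsofa_dist: dict[int, float] = Field(
        default_factory=lambda: {0: 0.467, 1: 0.336, 2: 0.150, 3: 0.047}
    )
    vasopressors: float = 0.093
    ventilation: float = 0.056
    syndrome_freq: dict[str, float] = Field(default_factory=_default_syndromes)
    regimen_freq: dict[str, float] = Field(default_factory=_default_regimen_freq)
    vancomycin_rate: float = 0.103
    azithromycin_rate: float = 0.084
    metronidazole_rate: float = 0.084

    #: baseline probability of a documented prior resistant isolate (per
    #: agent, preceding year); raised on the log-odds scale by recent
    #: hospitalization and antibiotic exposure
    prior_resistance_base: float = 0.06
    prior_resistance_hosp_lor: float = 0.9
    prior_resistance_abx_lor: float = 0.9

    mrsa_swab_rate: float = 0.598
    mrsa_positive_rate: float = 0.016

    culture_positive: float = 0.439
    relevant_given_positive: float = 0.787
    blood_given_positive: float = 0.46
    nonblood_given_blood: float = 0.29

    #: rates of ineligibility features, exercising the screening module
    palliative_rate: float = 0.02
    pregnancy_rate: float = 0.005
    recent_antibiotics_rate: float = 0.05
    prior_positive_culture_rate: float = 0.03
    culture_window_violation_rate: float = 0.04
    culture_missing_rate: float = 0.01
    repeat_patient_rate: float = 0.03

    ground_truth: dict[str, dict[str, float]] = Field(default_factory=default_ground_truth)
    start_date: datetime = datetime(2021, 11, 1, 8, 0)

    @model_validator(mode="after")
    def _validate_tables(self) -> "CohortSpec":
        for name, table in (("qsofa_dist", self.qsofa_dist), ("syndrome_freq", self.syndrome_freq)):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(f"{name} must sum to 1 (got {total:.6f})")
            if any(p < 0 for p in table.values()):
                raise ValidationError(f"{name} contains negative probabilities")
        if any(w < 0 for w in self.regimen_freq.values()) or not self.regimen_freq:
            raise ValidationError("regimen_freq must be a non-empty non-negative table")
        for agent in DEFAULT_CASCADE:
            if agent not in self.ground_truth:
                raise ValidationError(f"ground_truth missing cascade agent {agent!r}")
        return self


@dataclass
class SyntheticEpisode:
    """A generated episode together with its latent truth."""

    episode: PatientEpisode
    true_susceptibility: dict[str, int]
    true_probabilities: dict[str, float]
    cultures: list[CultureResult]


def _normalize(table: dict) -> tuple[list, np.ndarray]:
    keys = list(table.keys())
    w = np.array([table[k] for k in keys], dtype=float)
    return keys, w / w.sum()


def generate_cohort(spec: CohortSpec) -> list[SyntheticEpisode]:
    """Generate a cohort of synthetic episodes.

    Column-wise draw order (one vectorized draw per field): age, sex,
    hospital-acquired flag, prior hospitalization / ICU / antibiotics,
    per-agent prior resistance (cascade order), qSOFA, vasopressors,
    ventilation, syndrome, primary agent, vancomycin/azithromycin/
    metronidazole add-ons, MRSA swab (presence, age, result), timestamps,
    exclusion flags, repeat-patient flag, latent per-agent susceptibility
    (cascade order), culture outcome (positivity, relevance, specimens).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    registry = default_registry()
    cascade = list(registry.cascade)

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 105.0)
    female = rng.random(n) < spec.female
    hosp_acq = rng.random(n) < spec.hospital_acquired
    prior_hosp = rng.random(n) < spec.prior_hospitalization_90d
    prior_icu = rng.random(n) < spec.prior_icu_90d
    prior_abx = rng.random(n) < spec.prior_antibiotic_exposure_90d

    base_lor = np.log(spec.prior_resistance_base / (1 - spec.prior_resistance_base))
    res_logit = (
        base_lor
        + spec.prior_resistance_hosp_lor * prior_hosp
        + spec.prior_resistance_abx_lor * prior_abx
    )
    res_p = 1.0 / (1.0 + np.exp(-res_logit))
    prior_resistance = {a: rng.random(n) < res_p for a in cascade}

    qs_keys, qs_p = _normalize(spec.qsofa_dist)
    qsofa = rng.choice(np.array(qs_keys, dtype=int), size=n, p=qs_p)
    vaso = rng.random(n) < spec.vasopressors
    vent = rng.random(n) < spec.ventilation

    syn_keys, syn_p = _normalize(spec.syndrome_freq)
    syndrome = rng.choice(np.array(syn_keys, dtype=object), size=n, p=syn_p)

    reg_keys, reg_p = _normalize(spec.regimen_freq)
    primary = rng.choice(np.array(reg_keys, dtype=object), size=n, p=reg_p)
    add_vanco = rng.random(n) < spec.vancomycin_rate
    add_azithro = rng.random(n) < spec.azithromycin_rate
    add_metro = rng.random(n) < spec.metronidazole_rate

    has_swab = rng.random(n) < spec.mrsa_swab_rate
    swab_age_days = rng.uniform(1, 60, n)
    swab_positive = rng.random(n) < spec.mrsa_positive_rate

    abx_offset_h = rng.uniform(0, 24 * 30, n)  # episode start over ~1 month
    culture_offset_min = rng.uniform(-600, 600, n)
    window_violation = rng.random(n) < spec.culture_window_violation_rate
    violation_offset_min = rng.uniform(13 * 60, 48 * 60, n) * np.where(
        rng.random(n) < 0.5, 1, -1
    )
    culture_missing = rng.random(n) < spec.culture_missing_rate
    assess_delay_h = rng.uniform(1, 20, n)

    palliative = rng.random(n) < spec.palliative_rate
    pregnant = (rng.random(n) < spec.pregnancy_rate) & female & (age < 50)
    recent_abx = rng.random(n) < spec.recent_antibiotics_rate
    recent_abx_gap_h = rng.uniform(1, 71, n)
    prior_pos_culture = rng.random(n) < spec.prior_positive_culture_rate
    repeat_patient = rng.random(n) < spec.repeat_patient_rate

    # latent susceptibility from the ground-truth model
    true_p = np.empty((n, len(cascade)))
    for j, agent in enumerate(cascade):
        coefs = spec.ground_truth[agent]
        lp = (
            coefs["intercept"]
            + coefs["age_centered"] * (age - AGE_CENTER)
            + coefs["female"] * female
            + coefs["prior_hospitalization_90d"] * prior_hosp
            + coefs["prior_icu_90d"] * prior_icu
            + coefs["prior_antibiotic_exposure_90d"] * prior_abx
            + coefs["prior_resistance_same_agent_1y"] * prior_resistance[agent]
        )
        true_p[:, j] = 1.0 / (1.0 + np.exp(-lp))
    susceptible = rng.random((n, len(cascade))) < true_p

    cult_positive = rng.random(n) < spec.culture_positive
    cult_relevant = rng.random(n) < spec.relevant_given_positive
    cult_blood = rng.random(n) < spec.blood_given_positive
    cult_also_nonblood = rng.random(n) < spec.nonblood_given_blood

    episodes: list[SyntheticEpisode] = []
    for i in range(n):
        t_abx = spec.start_date + timedelta(hours=float(abx_offset_h[i]))
        if culture_missing[i]:
            t_culture = None
        elif window_violation[i]:
            t_culture = t_abx + timedelta(minutes=float(violation_offset_min[i]))
        else:
            t_culture = t_abx + timedelta(minutes=float(culture_offset_min[i]))
        t_assess = t_abx + timedelta(hours=float(assess_delay_h[i]))

        regimen = {str(primary[i])}
        if add_vanco[i]:
            regimen.add("vancomycin")
        if add_azithro[i]:
            regimen.add("azithromycin")
        if add_metro[i]:
            regimen.add("metronidazole")

        screens = []
        if has_swab[i]:
            screens.append(
                MRSAScreen(
                    result="positive" if swab_positive[i] else "negative",
                    collected=t_assess - timedelta(days=float(swab_age_days[i])),
                )
            )

        syndrome_i = str(syndrome[i])
        if syndrome_i == "pneumonia" and not hosp_acq[i]:
            syndrome_i = "community_acquired_pneumonia"

        resistant_set = {a for a in cascade if prior_resistance[a][i]}

        patient_idx = i - 1 if (repeat_patient[i] and i > 0) else i
        episode = PatientEpisode(
            episode_id=f"E{i:05d}",
            patient_id=f"P{patient_idx:05d}",
            age=float(age[i]),
            female=bool(female[i]),
            admitted=True,
            hospital_acquired=bool(hosp_acq[i]),
            prior_hospitalization_90d=bool(prior_hosp[i]),
            prior_icu_90d=bool(prior_icu[i]),
            prior_antibiotic_exposure_90d=bool(prior_abx[i]),
            prior_resistant_organisms_1y=resistant_set,
            qsofa=int(qsofa[i]),
            on_vasopressors=bool(vaso[i]),
            on_mechanical_ventilation=bool(vent[i]),
            neutropenic=syndrome_i == "febrile_neutropenia",
            syndrome=syndrome_i,
            current_regimen=regimen,
            timestamps=EpisodeTimestamps(
                first_antibiotic_time=t_abx,
                blood_culture_order_time=t_culture,
                assessment_time=t_assess,
            ),
            mrsa_screens=screens,
            prior_antibiotic_time=(
                t_abx - timedelta(hours=float(recent_abx_gap_h[i]))
                if recent_abx[i]
                else None
            ),
            palliative_care=bool(palliative[i]),
            pregnant=bool(pregnant[i]),
            prior_positive_culture_available=bool(prior_pos_culture[i]),
        )

        cultures: list[CultureResult] = []
        if cult_positive[i]:
            panel = {
                a: ("susceptible" if susceptible[i, j] else "resistant")
                for j, a in enumerate(cascade)
            }
            panel["vancomycin"] = "resistant"  # Gram-negative isolate
            relevant = bool(cult_relevant[i])
            specimens = (
                (["blood", "non_blood"] if cult_also_nonblood[i] else ["blood"])
                if cult_blood[i]
                else ["non_blood"]
            )
            for sp in specimens:
                cultures.append(
                    CultureResult(
                        episode_id=episode.episode_id,
                        specimen=sp,  # type: ignore[arg-type]
                        organism="enterobacterales",
                        clinically_relevant=relevant,
                        panel=dict(panel) if relevant else {},
                    )
                )

        episodes.append(
            SyntheticEpisode(
                episode=episode,
                true_susceptibility={
                    a: int(susceptible[i, j]) for j, a in enumerate(cascade)
                },
                true_probabilities={a: float(true_p[i, j]) for j, a in enumerate(cascade)},
                cultures=cultures,
            )
        )
    return episodes


def make_training_table(cohort: list[SyntheticEpisode]) -> pd.DataFrame:
    """Long-format training table: one row per episode-agent pair, with the
    per-row resistance indicator resolved to that row's agent and the
    susceptibility indicator equal to the latent truth."""
    rows = []
    for syn in cohort:
        ep = syn.episode
        for agent, y in syn.true_susceptibility.items():
            rows.append(
                {
                    "episode_id": ep.episode_id,
                    "agent": agent,
                    "susceptible": int(y),
                    "age": ep.age,
                    "female": int(ep.female),
                    "prior_hospitalization_90d": int(ep.prior_hospitalization_90d),
                    "prior_icu_90d": int(ep.prior_icu_90d),
                    "prior_antibiotic_exposure_90d": int(ep.prior_antibiotic_exposure_90d),
                    "prior_resistance_same_agent_1y": int(
                        agent in ep.prior_resistant_organisms_1y
                    ),
                }
            )
    columns = [
        "episode_id",
        "agent",
        "susceptible",
        "age",
        "female",
        "prior_hospitalization_90d",
        "prior_icu_90d",
        "prior_antibiotic_exposure_90d",
        "prior_resistance_same_agent_1y",
    ]
    return pd.DataFrame(rows, columns=columns)
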