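"""End-to-end pipeline: simulate -> screen -> fit -> recommend -> classify
-> evaluate, with a deterministic artifact bundle on disk."""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .classify import SpectrumChange, classify_change
from .eligibility import EligibilityConfig, screen_cohort
from .engine import EngineConfig, Recommendation, recommend
from .episode import CultureResult, PatientEpisode
from .errors import AbxCascadeError
from .evaluate import AdequacyRecord, CohortSummary, summarize_cohort
from .io import episodes_to_frame, write_cultures, write_episodes
from .registry import AgentRegistry, default_registry
from .simulate import CohortSpec, SyntheticEpisode, generate_cohort, make_training_table
from .susceptibility import GNModelSet, fit_models

logger = logging.getLogger("abxcascade")


class RunConfig(BaseModel):
    """Configuration for one end-to-end run on a synthetic cohort."""

    seed: int = 0
    n: int = 400
    output_dir: Optional[str] = None
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    eligibility: EligibilityConfig = Field(default_factory=EligibilityConfig)
    engine: EngineConfig = Field(default_factory=EngineConfig)
    registry: AgentRegistry = Field(default_factory=default_registry)
    #: size of the separately generated historical cohort the susceptibility
    #: models are calibrated on before being applied to the study cohort
    training_n: int = 2000

    def resolved_cohort_spec(self) -> CohortSpec:
        return self.cohort.model_copy(update={"seed": self.seed, "n": self.n})

    def training_cohort_spec(self) -> CohortSpec:
        seed = (self.seed + 990_001) % 2**31
        return self.cohort.model_copy(update={"seed": seed, "n": self.training_n})


@dataclass
class PipelineResult:
    cohort: list[SyntheticEpisode]
    eligible: list[PatientEpisode]
    excluded: dict[str, list[str]]  # criterion -> episode ids
    models: GNModelSet
    recommendations: list[Recommendation]
    changes: list[SpectrumChange]
    summary: CohortSummary
    summary_payload: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full desk-scale study flow and (optionally) write artifacts.

    Deterministic for a given config: all randomness flows from the single
    seed, and the summary JSON contains no wall-clock values.
    """
    registry = config.registry
    spec = config.resolved_cohort_spec()

    cohort = generate_cohort(spec)
    episodes = [s.episode for s in cohort]
    logger.info("generated %d synthetic episodes (seed=%d)", len(episodes), spec.seed)

    decisions = screen_cohort(episodes, config.eligibility, registry)
    eligible = [ep for ep, d in zip(episodes, decisions) if d.eligible]
    excluded: dict[str, list[str]] = {}
    for ep, d in zip(episodes, decisions):
        for crit in sorted(d.failed_criteria):
            excluded.setdefault(crit, []).append(ep.episode_id)
            logger.info("excluded %s: %s", ep.episode_id, crit)
    if len(eligible) + sum(1 for d in decisions if not d.eligible) != len(episodes):
        raise AbxCascadeError("screening bookkeeping error: in != out + excluded")
    logger.info("eligible: %d / %d", len(eligible), len(episodes))

    # models are calibrated on an independent "historical" cohort drawn from
    # the same generating process, then applied prospectively
    training = make_training_table(generate_cohort(config.training_cohort_spec()))
    models = fit_models(training)
    logger.info("fitted %d agent models on %d training rows", len(models.models), len(training))

    eligible_ids = {ep.episode_id for ep in eligible}
    syn_by_id = {s.episode.episode_id: s for s in cohort}

    recommendations: list[Recommendation] = []
    changes: list[SpectrumChange] = []
    adequacy_records: list[AdequacyRecord] = []
    for ep in eligible:
        try:
            rec = recommend(ep, models, registry, config.engine)
            change = classify_change(
                ep.current_regimen, rec.regimen, registry, syndrome=ep.syndrome
            )
        except AbxCascadeError as exc:
            raise AbxCascadeError(
                f"stage 'recommend/classify' failed for episode {ep.episode_id}: {exc}"
            ) from exc
        recommendations.append(rec)
        changes.append(change)
        cultures = syn_by_id[ep.episode_id].cultures
        if any(c.clinically_relevant for c in cultures):
            adequacy_records.append(
                AdequacyRecord(
                    episode_id=ep.episode_id,
                    clinician_regimen=frozenset(ep.current_regimen),
                    algorithm_regimen=frozenset(rec.regimen),
                    isolates=tuple(cultures),
                )
            )

    summary = summarize_cohort(changes, adequacy_records, registry)

    payload = {
        "package_version": __version__,
        "seed": config.seed,
        "n_generated": len(episodes),
        "n_eligible": len(eligible),
        "n_excluded_by_criterion": {k: len(v) for k, v in sorted(excluded.items())},
        "arm_usage": {
            arm: sum(1 for r in recommendations if arm in r.arms)
            for arm in ("guideline", "gram_negative_model", "gram_positive_rule")
        },
        "summary": summary.to_dict(),
        "input_sha256": _cohort_hash(episodes),
    }

    result = PipelineResult(
        cohort=cohort,
        eligible=eligible,
        excluded=excluded,
        models=models,
        recommendations=recommendations,
        changes=changes,
        summary=summary,
        summary_payload=payload,
    )
    if config.output_dir is not None:
        _write_bundle(config, result)
    return result


def _cohort_hash(episodes: list[PatientEpisode]) -> str:
    csv_text = episodes_to_frame(episodes).to_csv(index=False)
    return hashlib.sha256(csv_text.encode()).hexdigest()


def _write_bundle(config: RunConfig, result: PipelineResult) -> None:
    import json

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_episodes([s.episode for s in result.cohort], out / "episodes.csv")
    cultures: list[CultureResult] = [c for s in result.cohort for c in s.cultures]
    write_cultures(cultures, out / "cultures.csv")
    result.models.save(out / "models.json")

    rec_rows = []
    for ep, rec, ch in zip(result.eligible, result.recommendations, result.changes):
        rec_rows.append(
            {
                "episode_id": ep.episode_id,
                "received": ";".join(sorted(ep.current_regimen)),
                "recommended": ";".join(sorted(rec.regimen)),
                "arms": ";".join(sorted(rec.arms)),
                "threshold": "" if rec.threshold is None else rec.threshold,
                "gp_directive": rec.gp_directive.value,
                "coverage_shortfall": rec.coverage_shortfall,
                "direction": ch.direction.value,
                "gn_steps": ch.gn_steps,
                "gp_change": ch.gp_change.value,
                "total_steps": ch.total_steps,
                "rationale": " | ".join(rec.trace),
            }
        )
    pd.DataFrame(rec_rows).to_csv(out / "recommendations.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(result.summary_payload, indent=2, sort_keys=True)
    )
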