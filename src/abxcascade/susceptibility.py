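"""Individualized Gram-negative susceptibility prediction.

One logistic-regression model per cascade agent predicts the probability
that the patient's (presumed Gram-negative) pathogen is susceptible to that
agent, from epidemiologic predictors (age, sex, prior hospitalization, prior
ICU stay, prior antibiotic exposure) and prior culture results (a prior
clinical isolate resistant to the same agent within the preceding year).

The logit link is isolated in :func:`inverse_link` so an alternative
parametric link could be swapped without touching the rest of the engine.
Age enters centered at 65 years for numeric stability.  Fitting is
maximum-likelihood via statsmodels; constant-outcome training sets raise
:class:`~abxcascade.errors.DegenerateFitError` instead of returning a
silently useless model.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .episode import PatientEpisode
from .errors import ConfigurationError, DegenerateFitError, ValidationError
from .registry import AgentRegistry

AGE_CENTER = 65.0

#: order of the coefficient vector, after the intercept
FEATURE_NAMES = (
    "age_centered",
    "female",
    "prior_hospitalization_90d",
    "prior_icu_90d",
    "prior_antibiotic_exposure_90d",
    "prior_resistance_same_agent_1y",
)


@dataclass(frozen=True)
class PatientFeatures:
    """Predictor bundle for the susceptibility models.

    ``prior_resistant_1y`` holds agent names for which a resistant clinical
    isolate was documented in the preceding year; the per-agent indicator is
    derived from membership at prediction time.
    """

    age: float
    female: int
    prior_hospitalization_90d: int
    prior_icu_90d: int
    prior_antibiotic_exposure_90d: int
    prior_resistant_1y: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for name in (
            "female",
            "prior_hospitalization_90d",
            "prior_icu_90d",
            "prior_antibiotic_exposure_90d",
        ):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"indicator {name} must be 0/1, got {v!r}")

    @classmethod
    def from_episode(cls, episode: PatientEpisode, registry: AgentRegistry) -> "PatientFeatures":
        resistant = frozenset(
            registry.canonical(a) for a in episode.prior_resistant_organisms_1y
        )
        return cls(
            age=episode.age,
            female=int(episode.female),
            prior_hospitalization_90d=int(episode.prior_hospitalization_90d),
            prior_icu_90d=int(episode.prior_icu_90d),
            prior_antibiotic_exposure_90d=int(episode.prior_antibiotic_exposure_90d),
            prior_resistant_1y=resistant,
        )

    def encode(self, agent: str) -> np.ndarray:
        """Feature vector in FEATURE_NAMES order (no intercept column)."""
        return np.array(
            [
                self.age - AGE_CENTER,
                self.female,
                self.prior_hospitalization_90d,
                self.prior_icu_90d,
                self.prior_antibiotic_exposure_90d,
                int(agent in self.prior_resistant_1y),
            ],
            dtype=float,
        )


def inverse_link(linear_predictor: np.ndarray | float) -> np.ndarray | float:
    """Inverse of the model link: logistic (expit)."""
    return expit(linear_predictor)


@dataclass
class AgentModel:
    """Fitted (or specified) susceptibility model for one agent."""

    agent: str
    intercept: float
    coefficients: dict[str, float]
    n: Optional[int] = None
    converged: bool = True
    standard_errors: Optional[dict[str, float]] = None

    def coefficient_vector(self, feature_names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        missing = [f for f in feature_names if f not in self.coefficients]
        if missing:
            raise ValidationError(
                f"model for {self.agent!r} lacks coefficients for {missing}"
            )
        return np.array([self.coefficients[f] for f in feature_names], dtype=float)


@dataclass
class GNModelSet:
    """One susceptibility model per cascade agent."""

    models: dict[str, AgentModel]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __getitem__(self, agent: str) -> AgentModel:
        return self.models[agent]

    def __contains__(self, agent: str) -> bool:
        return agent in self.models

    # -- persistence ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "agents": {
                a: {
                    "intercept": m.intercept,
                    "coefficients": m.coefficients,
                    "n": m.n,
                    "converged": m.converged,
                }
                for a, m in self.models.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GNModelSet":
        payload = json.loads(text)
        models = {
            a: AgentModel(
                agent=a,
                intercept=spec["intercept"],
                coefficients=dict(spec["coefficients"]),
                n=spec.get("n"),
                converged=spec.get("converged", True),
            )
            for a, spec in payload["agents"].items()
        }
        return cls(models=models, feature_names=tuple(payload["feature_names"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GNModelSet":
        return cls.from_json(Path(path).read_text())


def predict_susceptibility(features: PatientFeatures, model: AgentModel) -> float:
    """Probability the pathogen is susceptible to ``model.agent``.

    Inverse-logit of intercept + x'beta; strictly increasing in the linear
    predictor and bounded in (0, 1) for finite inputs.
    """
    x = features.encode(model.agent)
    beta = model.coefficient_vector(FEATURE_NAMES)
    if x.shape != beta.shape:
        raise ValidationError(
            f"feature/coefficient dimension mismatch: {x.shape} vs {beta.shape}"
        )
    return float(inverse_link(model.intercept + x @ beta))


def coverage_profile(
    features: PatientFeatures,
    models: GNModelSet,
    registry: AgentRegistry,
) -> dict[str, float]:
    """Per-cascade-agent susceptibility probabilities for one patient."""
    profile: dict[str, float] = {}
    for agent in registry.cascade:
        if agent not in models:
            raise ConfigurationError(f"no fitted model for cascade agent {agent!r}")
        profile[agent] = predict_susceptibility(features, models[agent])
    return profile


TRAINING_COLUMNS = ("agent", "susceptible", "age") + tuple(
    f for f in FEATURE_NAMES if f not in ("age_centered",)
)


def fit_models(training: pd.DataFrame, *, maxiter: int = 200) -> GNModelSet:
    """Fit one logistic model per agent from a long-format training table.

    ``training`` needs one row per episode-agent pair with columns ``agent``,
    ``susceptible`` (0/1), ``age`` and the 0/1 indicator features of
    ``FEATURE_NAMES`` (``prior_resistance_same_agent_1y`` already resolved to
    the row's agent).  Raises :class:`DegenerateFitError` when an agent's
    outcome is single-class; non-convergence is flagged on the model, never
    silent.
    """
    missing = [c for c in TRAINING_COLUMNS if c not in training.columns]
    if missing:
        raise ValidationError(f"training table missing columns: {missing}")
    if training[list(TRAINING_COLUMNS)].isna().any().any():
        raise ValidationError("training table contains missing values")

    models: dict[str, AgentModel] = {}
    for agent, grp in training.groupby("agent", sort=True):
        y = grp["susceptible"].to_numpy(dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateFitError(
                str(agent), f"outcome is constant ({int(classes[0])}) in {len(y)} rows"
            )
        X = np.column_stack(
            [
                grp["age"].to_numpy(dtype=float) - AGE_CENTER,
                *(grp[f].to_numpy(dtype=float) for f in FEATURE_NAMES[1:]),
            ]
        )
        X = sm.add_constant(X, has_constant="add")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise DegenerateFitError(
                str(agent), f"singular or separated design in {len(y)} rows ({exc})"
            ) from exc
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        models[str(agent)] = AgentModel(
            agent=str(agent),
            intercept=float(params[0]),
            coefficients={f: float(b) for f, b in zip(FEATURE_NAMES, params[1:])},
            n=int(len(y)),
            converged=converged,
            standard_errors={
                "intercept": float(bse[0]),
                **{f: float(b) for f, b in zip(FEATURE_NAMES, bse[1:])},
            },
        )
    return GNModelSet(models=models)


# -- calibration utilities --------------------------------------------


def reliability_curve(
    y_true: np.ndarray, p_pred: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Decile reliability table: mean predicted vs observed rate per bin."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(p_pred, dtype=float)
    if y.shape != p.shape:
        raise ValidationError("y_true and p_pred must have equal length")
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = [
        {"bin": i, "n": len(idx), "mean_predicted": p[idx].mean(), "observed_rate": y[idx].mean()}
        for i, idx in enumerate(bins)
        if len(idx) > 0
    ]
    return pd.DataFrame(rows)


def calibration_slope(y_true: np.ndarray, p_pred: np.ndarray, n_bins: int = 10) -> float:
    """Count-weighted least-squares slope of observed on predicted rates
    across reliability-curve bins; ~1 for a well-calibrated model."""
    curve = reliability_curve(y_true, p_pred, n_bins=n_bins)
    w = curve["n"].to_numpy(dtype=float)
    x = curve["mean_predicted"].to_numpy()
    yb = curve["observed_rate"].to_numpy()
    xbar = np.average(x, weights=w)
    ybar = np.average(yb, weights=w)
    denom = np.average((x - xbar) ** 2, weights=w)
    if denom == 0:
        raise ValidationError("degenerate reliability curve: constant predictions")
    return float(np.average((x - xbar) * (yb - ybar), weights=w) / denom)
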