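"""Cohort-level evaluation: category proportions, step-count summaries,
adequacy-of-coverage tables and exact tests.

Adequacy of a regimen for a culture-positive patient: every clinically
relevant isolate is susceptible in vitro to at least one agent of the
regimen (``not_tested`` never counts as coverage).  Clinician and algorithm
regimens are compared on 2x2 adequacy tables with a two-sided Fisher exact
test, stratified by specimen type (blood / non-blood / both).

Quartiles of the discrete step counts use the inclusive median-of-halves
convention.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .classify import Direction, SpectrumChange
from .episode import CultureResult
from .errors import UndefinedAdequacyError, ValidationError
from .registry import AgentRegistry, default_registry

# -- adequacy ----------------------------------------------------------


def regimen_adequacy(
    regimen: Iterable[str],
    isolates: Sequence[CultureResult],
    registry: Optional[AgentRegistry] = None,
) -> bool:
    """True iff every clinically relevant isolate is susceptible to at
    least one regimen agent.  Raises :class:`UndefinedAdequacyError` when
    there is no relevant isolate (the patient is excluded from adequacy
    denominators, never silently counted)."""
    registry = registry or default_registry()
    relevant = [iso for iso in isolates if iso.clinically_relevant]
    if not relevant:
        raise UndefinedAdequacyError("no clinically relevant isolate")
    agents = {registry.canonical(a) for a in regimen}
    for iso in relevant:
        panel = {registry.canonical(a): r for a, r in iso.panel.items()}
        if not any(panel.get(a) == "susceptible" for a in agents):
            return False
    return True


@dataclass(frozen=True)
class AdequacyTable:
    """2x2 counts: rows clinician/algorithm, columns adequate/inadequate."""

    clinician_adequate: int
    clinician_inadequate: int
    algorithm_adequate: int
    algorithm_inadequate: int

    def __post_init__(self):
        if min(self.as_tuple()) < 0:
            raise ValidationError("adequacy counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.clinician_adequate,
            self.clinician_inadequate,
            self.algorithm_adequate,
            self.algorithm_inadequate,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.clinician_adequate, self.clinician_inadequate],
                [self.algorithm_adequate, self.algorithm_inadequate],
            ],
            dtype=int,
        )

    @property
    def n_patients(self) -> int:
        return self.clinician_adequate + self.clinician_inadequate


# -- Fisher's exact test ----------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    degenerate: bool = False


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def fisher_exact_two_sided(
    table: "AdequacyTable | np.ndarray | Sequence[Sequence[int]]",
    *,
    rel_tol: float = 1e-7,
) -> FisherResult:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums, over the hypergeometric support with the observed margins, the
    probabilities of all tables no more probable than the observed one
    (with relative tolerance ``rel_tol`` on the comparison, so exact
    probability ties are included despite floating-point rounding).
    A zero margin makes the table degenerate: p is defined as 1 and flagged.
    """
    if isinstance(table, AdequacyTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("table counts must be integers")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValidationError("table counts must be non-negative")

    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return FisherResult(p_value=1.0, degenerate=True)

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    log_pmf = (
        _log_comb(c1, support) + _log_comb(n - c1, r1 - support) - _log_comb(n, r1)
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return FisherResult(p_value=min(1.0, p), degenerate=False)


# -- summaries ---------------------------------------------------------


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) by the inclusive median-of-halves convention:
    for odd n the middle value belongs to both halves."""
    xs = sorted(values)
    n = len(xs)
    if n == 0:
        raise ValidationError("median_iqr of empty sequence")

    def med(seq: Sequence[float]) -> float:
        m = len(seq)
        mid = m // 2
        return float(seq[mid]) if m % 2 else (seq[mid - 1] + seq[mid]) / 2.0

    if n % 2:
        lower, upper = xs[: n // 2 + 1], xs[n // 2 :]
    else:
        lower, upper = xs[: n // 2], xs[n // 2 :]
    return med(xs), med(lower), med(upper)


@dataclass(frozen=True)
class AdequacyRecord:
    """Adequacy inputs for one culture-positive patient."""

    episode_id: str
    clinician_regimen: frozenset[str]
    algorithm_regimen: frozenset[str]
    isolates: tuple[CultureResult, ...]


@dataclass
class StratumAdequacy:
    table: AdequacyTable
    p_value: float
    degenerate: bool
    clinician_proportion: float
    algorithm_proportion: float


@dataclass
class CohortSummary:
    """Evaluation outputs over one classified cohort."""

    n: int
    counts: dict[str, int]
    proportions: dict[str, float]
    #: direction -> (median, q1, q3) of total step counts, where defined
    steps: dict[str, Optional[tuple[float, float, float]]]
    step_distributions: dict[str, dict[int, int]]
    adequacy: dict[str, StratumAdequacy] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": self.counts,
            "proportions": self.proportions,
            "steps": {
                k: (None if v is None else {"median": v[0], "q1": v[1], "q3": v[2]})
                for k, v in self.steps.items()
            },
            "step_distributions": {
                k: {str(s): c for s, c in sorted(v.items())}
                for k, v in self.step_distributions.items()
            },
            "adequacy": {
                k: {
                    "table": list(map(int, v.table.as_tuple())),
                    "p_value": v.p_value,
                    "degenerate": v.degenerate,
                    "clinician_proportion": v.clinician_proportion,
                    "algorithm_proportion": v.algorithm_proportion,
                    "n_patients": v.table.n_patients,
                }
                for k, v in self.adequacy.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _adequacy_stratum(
    records: Sequence[AdequacyRecord],
    specimen: Optional[str],
    registry: AgentRegistry,
) -> Optional[StratumAdequacy]:
    """Build one stratum table.  ``specimen`` None selects patients with
    relevant isolates in both specimen types, judged against all of them."""
    rows = []
    for rec in records:
        relevant = [i for i in rec.isolates if i.clinically_relevant]
        blood = [i for i in relevant if i.specimen == "blood"]
        non_blood = [i for i in relevant if i.specimen == "non_blood"]
        if specimen == "blood":
            subset = blood
        elif specimen == "non_blood":
            subset = non_blood
        else:
            subset = relevant if (blood and non_blood) else []
        if not subset:
            continue
        rows.append(
            (
                regimen_adequacy(rec.clinician_regimen, subset, registry),
                regimen_adequacy(rec.algorithm_regimen, subset, registry),
            )
        )
    if not rows:
        return None
    clin = sum(1 for c, _ in rows if c)
    algo = sum(1 for _, a in rows if a)
    table = AdequacyTable(
        clinician_adequate=clin,
        clinician_inadequate=len(rows) - clin,
        algorithm_adequate=algo,
        algorithm_inadequate=len(rows) - algo,
    )
    fisher = fisher_exact_two_sided(table)
    return StratumAdequacy(
        table=table,
        p_value=fisher.p_value,
        degenerate=fisher.degenerate,
        clinician_proportion=clin / len(rows),
        algorithm_proportion=algo / len(rows),
    )


def summarize_cohort(
    changes: Sequence[SpectrumChange],
    adequacy_records: Sequence[AdequacyRecord] = (),
    registry: Optional[AgentRegistry] = None,
) -> CohortSummary:
    """Category counts/proportions, per-direction step summaries, and
    specimen-stratified adequacy tables with exact-test p-values."""
    registry = registry or default_registry()
    if not changes:
        raise ValidationError("cannot summarize an empty cohort")

    counts = {d.value: 0 for d in Direction}
    for ch in changes:
        counts[ch.direction.value] += 1
    n = len(changes)
    proportions = {k: v / n for k, v in counts.items()}

    steps: dict[str, Optional[tuple[float, float, float]]] = {}
    dists: dict[str, dict[int, int]] = {}
    for d in (Direction.DE_ESCALATION, Direction.ESCALATION):
        vals = [ch.total_steps for ch in changes if ch.direction is d]
        dist: dict[int, int] = {}
        for v in vals:
            dist[v] = dist.get(v, 0) + 1
        dists[d.value] = dist
        steps[d.value] = median_iqr(vals) if vals else None

    adequacy: dict[str, StratumAdequacy] = {}
    if adequacy_records:
        for name, spec in (("blood", "blood"), ("non_blood", "non_blood"), ("both", None)):
            stratum = _adequacy_stratum(adequacy_records, spec, registry)
            if stratum is not None:
                adequacy[name] = stratum

    return CohortSummary(
        n=n,
        counts=counts,
        proportions=proportions,
        steps=steps,
        step_distributions=dists,
        adequacy=adequacy,
    )


def changes_from_step_distribution(
    de_escalation: Mapping[int, int], escalation: Mapping[int, int], no_change: int = 0
) -> list[SpectrumChange]:
    """Expand step-count histograms into SpectrumChange records (cascade
    steps only), convenient for summarizing published distributions."""
    from .classify import GPChange  # local import to keep module load light

    changes: list[SpectrumChange] = []
    for direction, dist in (
        (Direction.DE_ESCALATION, de_escalation),
        (Direction.ESCALATION, escalation),
    ):
        for n_steps, count in sorted(dist.items()):
            if count < 0 or n_steps < 0:
                raise ValidationError("step distribution entries must be non-negative")
            for _ in range(count):
                changes.append(
                    SpectrumChange(
                        direction=direction,
                        gn_steps=n_steps,
                        gp_change=GPChange.UNCHANGED,
                        total_steps=n_steps,
                        gn_direction=direction,
                    )
                )
    for _ in range(no_change):
        changes.append(
            SpectrumChange(
                direction=Direction.NO_CHANGE,
                gn_steps=0,
                gp_change=GPChange.UNCHANGED,
                total_steps=0,
                gn_direction=Direction.NO_CHANGE,
            )
        )
    return changes
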