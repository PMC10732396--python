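# abxcascade

Individualized empiric-antibiotic decision support for suspected early
sepsis — with a synthetic-cohort test bench.

## The problem

When sepsis is suspected, clinicians must start antibiotics before culture
results exist. The safe reflex is a broad-spectrum agent for everyone, but
most patients would be adequately covered by a narrower drug, and
indiscriminate broad-spectrum use drives resistance. `abxcascade`
implements a decision-support algorithm that individualizes the empiric
choice at the bedside, using only information available at presentation:
demographics, recent healthcare exposure, prior culture results and MRSA
surveillance swabs.

It is written for antimicrobial-stewardship researchers and methodologists
who want to study, stress-test or extend this class of algorithm. Because
real episode-level data cannot be shipped, the package includes a
first-class synthetic cohort generator with a known ground-truth
susceptibility model, so every component — and the pipeline end to end —
is testable against truth.

## The algorithm

Gram-negative agents are ordered on an a-priori spectrum cascade,
narrowest to broadest:

```
ciprofloxacin < ceftriaxone < ceftazidime < piperacillin-tazobactam < meropenem
```

For each eligible episode:

1. **Guideline arm.** Syndromes treated by a standard empiric regimen
   regardless of individual risk (cellulitis, community-acquired
   pneumonia, meningitis) receive the local guideline regimen directly.
2. **Gram-negative model arm.** For every other syndrome, one logistic
   regression per cascade agent predicts the probability that the
   patient's pathogen is susceptible:

   P(S_a = 1 | x) = expit(beta_0a + x' beta_a),

   where x contains age (centered at 65), sex, prior hospitalization and
   ICU stay within 90 days, prior antibiotic exposure, and an indicator of
   a prior isolate resistant to agent *a* in the preceding year. The
   engine recommends the narrowest agent whose predicted coverage meets a
   severity-dependent threshold — 80% when qSOFA < 2, 90% when qSOFA >= 2
   or the patient is on vasopressors. If the syndrome demands (non-MRSA)
   Gram-positive coverage that the chosen agent lacks, the walk continues
   up the cascade.
3. **Gram-positive rule.** Vancomycin is added or stopped according to the
   most recent MRSA surveillance swab within a 90-day window; without a
   swab, the current vancomycin status is retained.

The received and recommended regimens are then compared on the cascade:
moving down (or stopping vancomycin/daptomycin) is *de-escalation*, moving
up (or adding them) is *escalation*; step counts are cascade-position
differences plus one step per vancomycin change. Cohort evaluation
reports category proportions, step medians with interquartile ranges, and
adequacy-of-coverage 2x2 tables (clinician vs algorithm regimen against
the isolated pathogens) with two-sided Fisher exact tests.

## Worked example

A 74-year-old woman with undifferentiated sepsis, qSOFA 1, recently
hospitalized, with ciprofloxacin- and ceftriaxone-resistant isolates in
the past year, currently on piperacillin-tazobactam:

```python
from datetime import datetime, timedelta
from abxcascade import (
    PatientEpisode, EpisodeTimestamps, ground_truth_model_set,
    recommend, classify_change, screen_episode,
)

t0 = datetime(2021, 11, 5, 12, 0)
episode = PatientEpisode(
    episode_id="E001", patient_id="P001",
    age=74, female=True, admitted=True,
    prior_hospitalization_90d=True,
    prior_resistant_organisms_1y={"ciprofloxacin", "ceftriaxone"},
    qsofa=1, syndrome="undifferentiated",
    current_regimen={"piperacillin-tazobactam"},
    timestamps=EpisodeTimestamps(
        first_antibiotic_time=t0,
        blood_culture_order_time=t0 - timedelta(hours=2),
        assessment_time=t0 + timedelta(hours=4),
    ),
)
print("eligible:", screen_episode(episode).eligible)
rec = recommend(episode, ground_truth_model_set())
print("threshold:", rec.threshold)
print("profile:", {a: round(p, 3) for a, p in rec.profile.items()})
print("recommended:", sorted(rec.regimen), "| arms:", sorted(rec.arms))
change = classify_change(episode.current_regimen, rec.regimen)
print("change:", change.direction.value, "| steps:", change.total_steps)
```

prints

```
eligible: True
threshold: 0.8
profile: {'ciprofloxacin': 0.213, 'ceftriaxone': 0.263, 'ceftazidime': 0.818, 'piperacillin-tazobactam': 0.876, 'meropenem': 0.952}
recommended: ['ceftazidime'] | arms: ['gram_negative_model']
change: de_escalation | steps: 1
```

The prior resistant isolates crush the predicted coverage of
ciprofloxacin and ceftriaxone, so the walk stops at ceftazidime — the
narrowest agent still above the 80% low-severity threshold — a one-step
de-escalation from the received piperacillin-tazobactam. (The bundled
`ground_truth_model_set()` carries simulation constants, not clinically
calibrated coefficients; fit your own with `fit_models`.)

## Command line

```bash
abxcascade simulate --n 500 --seed 1 --out sim/       # episodes, cultures, truth
abxcascade screen sim/episodes.csv --out screened.csv # eligibility columns
abxcascade fit sim/training.csv --out models.json     # per-agent logistic fits
abxcascade recommend screened.csv --models models.json --out recs.csv
abxcascade evaluate recs.csv --cultures sim/cultures.csv --out summary.json
abxcascade run --n 500 --seed 1 --out run/            # all of the above
```

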