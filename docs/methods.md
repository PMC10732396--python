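# Methods

This note records the model, the fixed conventions, and the design choices
behind `abxcascade`, in enough detail to reproduce or modify any of them.

## Decision model

### Eligibility screen

An episode enters the analysis when the patient is an adult (>= 18 y),
admitted, receiving at least one eligible systemic antibiotic, and had
blood cultures ordered within +/- 12 hours of the first antibiotic dose.
Exclusions: prior enrolment of the same patient, palliative care,
pregnancy, other inpatient antibiotic use within the prior 72 hours, and a
positive index-event culture already available at assessment. Conventions:

* All criteria are evaluated independently and every violation is
  reported; there is no short-circuiting.
* Timestamps are truncated to whole minutes before comparison and both
  window bounds are inclusive, so a culture ordered at exactly +12 h or
  −12 h qualifies.
* The eligible-antibiotic list defaults to every agent in the registry
  (the union of agents observed in clinical prescribing for this
  population); institutions are expected to override it, and all criteria
  parameters are configurable.
* Exclusion flags absent from the input default to "not documented",
  i.e. no exclusion — the behaviour of an observational chart screen.
* Within one processed dataset, the first eligible episode enrolls the
  patient and later episodes of that patient are excluded.

### Gram-negative susceptibility models

"Likelihood of susceptibility" is a probability, so the parametric family
is logistic regression (logit link); the link function is isolated in
`susceptibility.inverse_link` so another parametric link can be swapped
without touching the engine. One model per cascade agent, with predictors

| predictor | coding | note |
|---|---|---|
| age | years − 65, continuous | centered for numeric stability |
| female sex | 0/1 | |
| prior hospitalization | 0/1, 90-day lookback | |
| prior ICU stay | 0/1, 90-day lookback | |
| prior antibiotic exposure | 0/1, 90-day lookback | |
| prior resistant isolate, same agent | 0/1, 365-day lookback | per-agent indicator |

Lookback windows are configurable; the defaults above are the exposure
definitions the episode record carries. Fitting is maximum-likelihood via
`statsmodels` `Logit`; a constant outcome, a singular design or perfect
separation raises `DegenerateFitError` naming the agent, and
non-convergence is flagged on the model rather than silently ignored.
Coefficients serialize to JSON (agent → intercept + named coefficients).

No monotonicity is enforced across the cascade: a broader agent may have
lower predicted coverage (e.g. a patient with a prior
piperacillin-tazobactam-resistant isolate only); the cascade walk handles
that case naturally.

The package does not ship clinically calibrated coefficients.
`ground_truth_model_set()` exposes the synthetic generator's constants for
demonstration and testing, and is labelled non-clinical.

### Recommendation engine

Severity thresholds: predicted coverage must reach 0.80 for low-severity
patients and 0.90 for high severity. The high-severity predicate is
qSOFA >= 2 *or* vasopressor support. The boundary case qSOFA = 2 is not
covered by the verbal rule "<2 → 80%, >2 → 90%"; it is mapped to the high
threshold here because 2 is the conventional qSOFA high-risk cut-point.
The cutoff is configurable (`qsofa_high_cutoff`), and the test suite
exercises both readings.

Cascade walk: the narrowest agent with coverage >= threshold is selected
(weak inequality — exactly 0.80 qualifies at the low threshold; a strict
mode is available). When the syndrome requires non-MRSA Gram-positive
coverage (default list: skin/soft-tissue/bone, odontogenic) and the
selected agent lacks it (ciprofloxacin, ceftazidime), the walk continues
up the cascade to the next qualifying agent with Gram-positive activity.
If no agent reaches the threshold, the broadest agent is recommended and
a predicted-coverage shortfall is flagged in the rationale trace — the
algorithm never abstains for an eligible episode.

Guideline arm defaults (all configurable, standing in for local guideline
text that varies by institution): cellulitis → cefazolin;
community-acquired pneumonia → ceftriaxone + azithromycin (levofloxacin
treated as spectrum-equivalent by the classifier); meningitis/CNS
infection → ceftriaxone + vancomycin.

MRSA rule: the most recent surveillance swab within a 90-day lookback
(not fixed by the verbal description; configurable) governs vancomycin —
positive → add/continue, negative → stop/withhold. With no in-window swab
the current vancomycin status is retained: absent surveillance data is
not treated as licence to stop empiric MRSA coverage. Vancomycin that is
part of a guideline regimen (meningitis) is retained even after a
negative swab, since it targets resistant pneumococci there, not MRSA.
The Gram-positive arm is recorded as "applied" exactly when an in-window
swab exists.

Adjunct rule: for intra-abdominal, hepatobiliary and odontogenic sepsis,
metronidazole is added when the selected agent lacks anaerobic activity
(everything below piperacillin-tazobactam). Adjuncts never change the
spectrum level.

### Spectrum classification

Regimens are normalized to three coordinates: a Gram-negative cascade
level (the maximum position among GN-active agents), a Gram-positive flag
(vancomycin/daptomycin), and an adjunct set (azithromycin, metronidazole,
level-neutral). Equivalence classes collapse to zero steps: ertapenem ~
meropenem, gentamicin ~ ceftazidime, and levofloxacin ~ the
ceftriaxone/azithromycin level in the community-acquired-pneumonia
context (elsewhere levofloxacin sits at ciprofloxacin's level — same
class — an extension beyond the defined equivalences).

Narrow-spectrum agents without a cascade position (cefazolin, ampicillin,
cephalexin, clindamycin, doxycycline) occupy a "below-cascade" tier at
level 0, one step below ciprofloxacin. This tier is an extension: the
source cascade does not define their level, but received regimens contain
them, so the classifier must place them somewhere; one step to/from the
nearest cascade endpoint is the most conservative consistent choice.

Steps: `gn_steps` is the absolute level difference; a vancomycin or
daptomycin add/stop contributes one further step to `total_steps` (this
is how a five-step change can exceed the four-step maximum of a
five-agent cascade). Mixed-direction changes (cascade down, vancomycin
added — or the reverse) receive a single category by precedence:
escalation wins by default, on the conservative view that any broadening
is an escalation; the precedence is configurable and both axes are
retained in the output.

### Cohort evaluation

Adequacy: a regimen is adequate for a patient when *every* clinically
relevant isolate is susceptible in vitro to at least one regimen agent
(the all-isolates rule; `not_tested` never counts as coverage). Patients
with no clinically relevant isolate are excluded from adequacy
denominators via an explicit undefined-adequacy signal, never silently
counted. Relevance is an input flag, not inferred. Tables are stratified
by specimen type: relevant blood isolates, relevant non-blood isolates,
and patients with both (judged against all their relevant isolates).

Fisher's exact test (two-sided) is computed by direct summation of
hypergeometric probabilities no greater than the observed table's, with a
relative tie tolerance of 1e-7 so exact probability ties survive
floating-point rounding; the pmf is evaluated from log-gamma functions,
vectorized over the support. A zero margin makes the table degenerate:
p is defined as 1 and flagged. The test suite checks the implementation
against an exact integer-arithmetic enumeration oracle for every 2x2
table with total count <= 60, and against `scipy.stats.fisher_exact` on
random tables.

Quartiles of discrete step counts use the inclusive median-of-halves
convention (for odd n the middle value belongs to both halves), which is
the convention that reproduces the published quartiles on the published
step distributions — the governing check.

The clinician-vs-algorithm adequacy comparison uses the unpaired 2x2
Fisher test, which is the named analysis; a McNemar-style paired variant
would also be defensible for these data but is deliberately not used.

## Synthetic cohort generator

The generator emulates the marginal structure of a tertiary-care
early-sepsis cohort: age N(66.3, 19.7²) truncated to [18, 105], 39.3%
female, 31.8% prior hospitalization, 8.4% prior ICU, qSOFA distribution
(46.7 / 33.6 / 15.0 / 4.7%), 9.3% vasopressors, a ten-syndrome mix, MRSA
swab availability 59.8% with 1.6% positivity, culture positivity 43.9%
with 78.7% clinical relevance, and clinician regimens drawn from observed
prescribing frequencies (one primary agent from the 13-agent non-adjunct
frequency table; vancomycin, azithromycin and metronidazole added
independently at their marginal rates — observed counts sum to more than
the cohort because patients receive combinations). The 14%
skin/soft-tissue share is split 7.5% cellulitis (guideline arm — matching
the observed cefazolin recommendation share) and 6.5% other; pneumonia is
routed to the community-acquired-pneumonia guideline only when not
hospital-acquired. Prior antibiotic exposure (25%) and the prior-resistance
model (baseline 6% per agent, log-odds +0.9 for recent hospitalization
and +0.9 for recent antibiotics) are not pinned by the emulated marginals
and were chosen once as typical of such cohorts.

Latent susceptibility is drawn per agent from the ground-truth logistic
model conditional on the features; correlation across agents is induced
solely through shared features, with no residual correlation — the
simplest structure consistent with the model family, and a known
limitation (real resistance mechanisms induce extra cross-agent
correlation, e.g. ESBL phenotypes). Ground-truth intercepts rise along
the cascade (baseline susceptibility 0.80 → 0.97), the per-agent
prior-resistance coefficient is −2.2, and exposure coefficients are
−0.5 to −0.7.

Small rates of exclusion features (palliative 2%, pregnancy 0.5%, recent
antibiotics 5%, available prior culture 3%, culture-window violations 4%,
missing culture order 1%, repeat patients 3%) are injected so the
screening module is exercised end to end.

All randomness flows from one seeded NumPy `default_rng`; draws are
column-wise in a documented fixed order, making cohorts bit-reproducible
for a given (spec, seed). What passing tests on this generator show is
that the *machinery* is correct — recovery of known coefficients,
calibration against known probabilities, correct plumbing of every rule.
They do not validate the clinical performance of any coefficient set on
real patients, where feature distributions, missingness and residual
correlation differ.

## Pipeline and problem sizes

The end-to-end `run` fits the susceptibility models on a separately
generated "historical" cohort (default 2,000 episodes, seed derived from
the run seed) and applies them prospectively to the study cohort — small
study cohorts cannot support their own fits (meropenem susceptibility
~0.97 separates at small n), and this mirrors how such models are
deployed. Default problem sizes: 10,000 episodes for marginal checks,
5,000 for parameter recovery and held-out calibration (every coefficient
within 3 standard errors of truth; decile reliability slope in
[0.9, 1.1]), 10,000 random profiles for the cascade-walk oracle, 400–1,000
episodes for end-to-end runs. These sizes give stable Monte-Carlo checks
while keeping the full suite fast on one CPU.

## Known limitations

* No dosing, renal adjustment, allergy handling or route of
  administration; recommendations are agent sets only.
* The Gram-positive rule implements the MRSA-swab directive only; richer
  Gram-positive branching (e.g. enterococcal risk) is out of scope.
* The spectrum level of below-cascade agents and of levofloxacin outside
  pneumonia are package conventions, clearly flagged, not externally
  defined.
* Synthetic cohorts have no organism taxonomy, no time-varying
  colonization, and independent episodes; adequacy panels cover cascade
  agents plus vancomycin only.
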