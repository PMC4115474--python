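# cogniplan

Automatic planning of cognitive rehabilitation sessions for patients with
acquired brain injury (ABI).

After a stroke or traumatic brain injury, patients follow long computerized
rehabilitation programmes — typically 60 one-hour sessions of tasks that
each train one of 11 cognitive subfunctions (sustained/selective/divided
attention, visual/verbal/working memory, and five executive subfunctions).
Assembling those sessions by hand, task by task and difficulty knob by
difficulty knob, is slow and depends heavily on each therapist's habits.
`cogniplan` implements an automatic therapy planner for this setting,
together with a synthetic cohort-and-response simulator for evaluating it.
It is aimed at rehabilitation-informatics researchers and platform
developers who need a reproducible, testable planning core.

## The method

**Profiles.** A neuropsychological assessment is normalised (z-scores
against age/education-stratified norms, one severity level per SD below the
mean) into a *cognitive profile*: an impairment level 0 (normality) to 4
(very severe) per subfunction. A treatment counts as an improvement when at
least one of the three function-level impairments strictly decreases and
none increases.

**Clustering.** Patients are grouped by profile with a diagonal-covariance
Gaussian mixture fitted by expectation-maximization (EM); the number of
components is chosen by 10-fold cross-validated held-out log-likelihood.
Clusters define who counts as a "similar patient" for the scoring criteria,
and the model is refit whenever a new patient starts treatment.

**Scoring.** For one patient, every catalog task receives

- a usage score *U* ∈ {0..4} — quartile rank of how often similar patients
  ran the task (0 if never used),
- an improvement score *I* ∈ [0, 4] — mean PRE→POST improvement of similar
  patients who ran it, on the task's designated subfunction plus a
  discounted contribution of the other cognitive functions,
- a clinical score *IL&CC* — the dot product of the patient's impairment
  levels with the task's clinician-rated criteria vector,

combined as the Global Suitability Score

```
GSS = U·ku + I·ki + IL&CC·kc
```

The catalog, ordered by GSS, is split into suitability quartiles SQ1–SQ4.

**Scheduling.** Sessions are planned in blocks of ten; tasks are drawn
cyclically 3×SQ1, 2×SQ2, 2×SQ3, 1×SQ4 until the 60-minute budget is
reached. Each task's parameter space is enumerated and split into
difficulty quartiles DQ1 (easiest) – DQ4 by total difficulty weight; the
quartile scheduled depends on the patient's impairment, adjusted between
blocks by the mean execution result per subfunction (MERS): +1 impairment
level if MERS < 65, −1 if 65 ≤ MERS ≤ 85, −2 if MERS > 85. Execution
scores in [65, 85] are *therapeutic*; a task scoring outside that band is
re-launched one difficulty quartile easier (< 65) or harder (> 85). Planner
v1 schedules everything upfront from the PRE assessment; v2 re-plans every
block using MERS.

**Simulation.** Synthetic cohorts are drawn from archetype profiles; each
patient responds through a latent-ability logistic model where a difficulty
matching ability scores 75 in expectation, and ability grows slightly after
each therapeutic-range execution. `run_closed_loop` alternates planning and
simulated execution, letting the two planner versions be compared end to
end.

## Worked example

```python
from cogniplan import ABI_TAXONOMY, BINGO, CognitiveProfile, clinical_score
from cogniplan import build_difficulty_model, score_catalog, assemble_block
from cogniplan import synthetic_catalog

levels = dict(zip(ABI_TAXONOMY.subfunction_names,
                  (3, 2, 3, 2, 1, 3, 1, 0, 1, 2, 0)))
patient = CognitiveProfile(levels)

print(clinical_score(patient, BINGO))
# 19   <- impairment x criteria summed over the 11 subfunctions:
#         sustained 3x4=12, selective 2x2=4, divided 3x1=3

model = build_difficulty_model(BINGO)
print(len(model.configurations))
# 30   <- 3 matrix dimensions x 5 presentation times x 2 levels

catalog = synthetic_catalog(n_tasks=24, seed=7)
breakdown = score_catalog(patient, catalog)
sq = {b.task_id: b.suitability_quartile for b in breakdown}
sessions = assemble_block(sq, catalog, patient, block_size=10, rng=0)
print(len(sessions), [q for q in (sq[t] for t in sessions[0].task_ids)])
# 10 [1, 1, 1, 2, 2, 3, 3, 4]   <- a 60-min session drawn 3/2/2/1 from SQ1..SQ4
```

The Bingo task (click the numbers appearing on a bingo card; trains
sustained attention) ships with the package as the reference catalog entry.

A full closed-loop comparison from the command line:

```bash
cogniplan --seed 1 simulate --version v1 --log-out v1.csv --summary-out v1.json
cogniplan --seed 1 simulate --version v2 --log-out v2.csv --summary-out v2.json
```

Each summary reports the infra/therapeutic/supra score fractions and the
fraction of patients whose profile improved; under the default response
model the adaptive v2 planner keeps a larger share of executions in the
therapeutic band than v1.

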