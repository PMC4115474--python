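# Methods

This note documents the models and procedures implemented in `cogniplan`,
the parameters that matter, and the design choices made where the problem
left the design open.

## Cognitive profiles and normalisation

The unit of analysis is an 11-dimensional *cognitive profile*: an integer
impairment level 0 (normality) … 4 (very severe) for each treatable
subfunction of attention (sustained, selective, divided), memory (visual,
verbal, working) and executive functioning (scheduling, inhibition,
flexibility, sequencing, categorization).

`normalize_assessment` turns raw test items into a profile in three steps:
(1) each item is z-scored against a normative mean/SD stratified by age
band and education level (the normative table is configuration-supplied,
as clinical norms are proprietary); (2) z-scores are averaged per
subfunction; (3) the mean z is banded at one severity level per standard
deviation below the norm (0 for z > −1, 1 for −2 < z ≤ −1, …, 4 for
z ≤ −4). The banding thresholds are a design choice: 1-SD clinical
severity bands are the standard convention that exactly spans a 5-point
scale. Function-level aggregates are the arithmetic mean of the function's
subfunction levels rounded half-up — the simplest order-preserving
summary; they are used only by the improvement criterion. Cohort files may
carry pre-banded 0–4 vectors directly, bypassing normalisation.

*Improvement* is deliberately strict: at least one function-level
impairment must strictly decrease and none may increase. It is
irreflexive and asymmetric on strictly improving pairs (property-tested).

## Mixture model over profiles

Patients are clustered with a Gaussian mixture over the 11 impairment
coordinates, fitted by EM:

- **Diagonal covariances.** 11 dimensions at clinical cohort sizes make
  full covariances unstable; diagonal components keep the fit
  well-conditioned and interpretable (a per-subfunction spread per
  cluster).
- **Variance floor 0.25.** Profiles are quantized to integer levels, so a
  component SD below half a level has no clinical meaning. Numerically the
  floor matters more than that: on lattice-valued data, EM with a loose
  floor places near-spike components on individual lattice values, and
  because held-out patients sit on the same lattice, cross-validated
  likelihood *rewards* this carving and the selected component count
  inflates with clinically meaningless clusters. Flooring each variance at
  (½ level)² = 0.25 caps the attainable density at the resolution of the
  scale and removes the artefact.
- **Initialisation** by k-means (3 restarts) from the explicit seed; all
  randomness flows from that seed, so fits are bit-reproducible.
- **Convergence** when the absolute log-likelihood change falls below
  `tol · max(1, |ll|)` (default `tol = 1e-6`, `max_iter = 200`). The
  log-likelihood trace is stored on the results object and is
  non-decreasing (asserted in tests); a fit that exhausts `max_iter` is
  returned flagged `converged=False`, never raised.
- **Model selection.** With `k=None`, K grows from 1 while the mean
  held-out log-likelihood over 10 cross-validation folds improves; ties
  and regressions stop the search. Identical profiles therefore select
  K = 1.

The module follows the model/results idiom: `ProfileMixture` holds data
and settings, `fit()` returns a `ProfileMixtureResults` with estimates,
diagnostics, `assign()` (posterior responsibilities for a new patient,
proportional to weight × component density) and `summary()`. Refitting on
cohort-plus-new-patient (`refit_with_patient`) mirrors the deployment
behaviour of recomputing clusters whenever a patient starts treatment. An
independent cross-check against scikit-learn's `GaussianMixture` (same
covariance structure and floor) runs in the test suite; the production
path is the package's own EM.

## Suitability scoring

All quartile operations share one primitive: order the items, cut into 4
contiguous groups with sizes differing by at most one, earlier groups
taking the remainder (95 tasks → 24/24/24/23). This rule is deterministic
and order-independent given the tie-breaks below.

- **Usage U ∈ {0..4}**: tasks executed by the patient's cluster are
  ranked by descending execution count and quartiled, 4 = most used,
  1 = least used, 0 = never used. Ties in count are promoted to the best
  group any equal-count task occupies, so equal evidence yields equal
  scores.
- **Improvement I ∈ [0, 4]**: over cluster patients who executed the
  task, the mean PRE−POST drop on the task's designated subfunction
  (Δp, subfunction level) and on the two other functions (Δo, function
  level) combine as `clamp(w_primary·Δp + w_other·Δo, 0, 4)`; 0 when no
  similar patient executed the task. The functional form is a design
  choice; weighting the designated subfunction fully (`w_primary = 1`)
  and the off-target functions at half (`w_other = 0.5`) keeps the score
  commensurable with the other 0–4 criteria while still crediting
  generalised improvement.
- **Clinical IL&CC**: Σ over the 11 subfunctions of patient impairment ×
  the task's clinician-rated criteria value. For the packaged Bingo task
  (criteria 4/2/1 on sustained/selective/divided attention) and the
  worked-example profile this gives 12 + 4 + 3 = 19.
- **GSS** = `U·ku + I·ki + IL&CC·kc`, with defaults `ku = ki = kc = 1`;
  the coefficients exist so clinicians can re-weight the criteria and all
  are configuration-overridable. GSS is monotone in each criterion
  (property-tested).
- **Suitability quartiles**: catalog sorted by descending GSS, ties by
  ascending task id, then the near-equal split. Ordering by id makes the
  assignment invariant to input permutation.

## Scheduling and difficulty adaptation

Each task's parameter space is enumerated as the cartesian product of its
parameter values; a configuration's difficulty is the sum of per-value
integer weights (0 = easiest value of each parameter). Configurations are
stable-sorted by total weight (ties keep the enumeration order, which is
lexicographic in parameter-value order) and quartiled into DQ1–DQ4. For
the packaged Bingo definition the harder direction is: larger matrix,
shorter presentation time, disordered layout — 30 configurations in
groups of 8/8/7/7.

Sessions are assembled per block (default 10 sessions × 60 minutes) by
drawing tasks cyclically 3×SQ1, 2×SQ2, 2×SQ3, 1×SQ4 — uniformly without
replacement within a session, with replacement across sessions. A drawn
task that no longer fits the session's duration budget closes the session
and opens the next one, so the draw cycle is never skipped; a demanded
quartile with no available task falls through to the next non-empty
quartile (logged). A task longer than a whole session is skipped with a
warning.

Difficulty selection maps (possibly adjusted) impairment *a* on the
task's designated subfunction to a target quartile `DQ = clamp(4 − a, 1,
4)` — severest impairment ⇒ easiest quartile, no impairment ⇒ hardest —
and samples uniformly within that quartile. For parameter spaces with
fewer than 4 configurations the nearest occupied quartile is used,
preferring the easier side.

Between blocks, performance feeds back through MERS, the mean execution
score per subfunction: impairment is adjusted +1 if MERS < 65
(tasks too hard), −1 if 65 ≤ MERS ≤ 85 (progressing), −2 if MERS > 85
(too easy), clamped to 0–4. Boundary scores 65 and 85 are treated as
therapeutic everywhere so the three ranges partition [0, 100]. Planner
**v1** schedules the whole treatment upfront from PRE alone (suitability
computed once); **v2** re-plans each block with the MERS adjustment. Both
are exposed for comparison.

Out-of-range executions are re-launched: one difficulty quartile easier
after an infra-therapeutic score, one harder after a supra-therapeutic
score (clamped at DQ1/DQ4), appended to the first later session in the
block with room for the task. One quartile is the smallest responsive
step; a block with no open session logs the event and stays unchanged.

## Synthetic cohorts and the response model

`generate_cohort` draws each patient from one of a set of archetypes
(uniform choice), adding Gaussian noise (default SD 0.3) to the archetype
mean vector, clamping to [0, 4] and rounding to integer levels; the
archetype label is retained as hidden ground truth. The default
archetypes (all-subfunction means 0.5 and 3.5) represent a mildly and a
severely impaired patient group with clear separation.

`simulate_execution` models a patient's score on a configured task with a
latent ability θ = (4 − impairment)/4 ∈ [0, 1] per subfunction and
normalised difficulty d = configuration weight / maximum weight:

```
E[score] = 100 · logistic(γ·(θ − d) + log 3)
```

The offset log 3 makes a perfectly matched difficulty (θ = d) score 75 in
expectation — the centre of the therapeutic band — so "well-matched
difficulty" lands therapeutic by construction. Defaults: slope γ = 5
(scores fall off over roughly two difficulty quartiles), additive score
noise SD 8 points (moderate trial-to-trial variability), learning
increment δ = 0.05 added to θ after each therapeutic-range execution
(learning only happens when difficulty is well matched — the premise the
planner is built on). The POST profile is read back from final abilities
by inverse banding, 4·(1 − θ) rounded to the integer scale.

`run_closed_loop` alternates planning and execution per block and
summarises range fractions and the improvement rate. Closed-loop runs are
bit-reproducible from the seed: each patient uses an independent seeded
substream.

What the simulator does *not* emulate: real patients' inter-session
variability and fatigue, therapist overrides, heterogeneous per-task
response curves, transfer between subfunctions, and manual planning
behaviour (a random-from-catalog baseline would stand in for the last).
Passing closed-loop tests therefore show that the adaptive machinery
behaves as designed under its own assumptions — not that the same
margins would appear in a clinical cohort, whose published range
percentages are well below the simulator's.

## Problem sizes and numerical choices

The default evaluation sizes were chosen as the smallest that exercise
the mechanisms clearly: cluster recovery at n = 200 patients (two
archetypes, 4+ SD separation), closed-loop comparisons over 20 paired
replicates of 4-patient cohorts, 24-task catalogs, 3 blocks of 10
sessions. The v1-vs-v2 comparison is directional (mean therapeutic
fraction of v2 ≥ v1): with learning enabled, v1's frozen difficulty
drifts supra-therapeutic while v2 follows the patient.

Degenerate inputs are handled explicitly: empty execution logs (usage 0,
MERS absent), empty quartiles (fall-through), single-configuration
parameter spaces (all DQ1), identical cohorts (K = 1), non-convergent EM
(flagged, not raised). Scores and profiles are validated at construction;
readers report the offending row, task or field by name.

## Known limitations

- The improvement criterion operates on banded integers, so small real
  changes below one severity level are invisible to it.
- Usage and improvement criteria assume a reasonably populated cluster
  history; cold-start patients are scored on clinical criteria alone.
- The scheduler treats task durations as fixed nominal minutes; real
  execution times vary.
- Re-launch extends a later session within its duration cap rather than
  replacing a scheduled entry; platforms that substitute instead will
  differ in session composition.
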