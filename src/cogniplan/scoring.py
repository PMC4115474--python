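"""Multi-criteria task suitability scoring.

For one patient, every task in the catalog is rated on four criteria, all on
(or scaled to) a 0-4 range except the combined clinical score:

* **usage score (U)** — how often patients of the same cluster executed the
  task: used tasks are ordered by execution count and split into quartiles,
  scoring 4 (most used) down to 1; never-used tasks score 0.
* **improvement score (I)** — the mean PRE->POST improvement of cluster
  patients who executed the task, on the subfunction the task is designed
  for, plus a discounted contribution from the other two cognitive
  functions; clamped to [0, 4].
* **clinical score (IL&CC)** — the dot product of the patient's impairment
  levels (IL) with the task's clinical criteria vector (CC) over the 11
  subfunctions.

These combine linearly into the Global Suitability Score

    GSS = U*ku + I*ki + IL&CC*kc

and the catalog, ordered by descending GSS, is cut into suitability
quartiles SQ1 (most suitable) .. SQ4 used by the session scheduler.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .profile import CognitiveProfile
from .quartiles import quartile_of
from .tasks import ExecutionRecord, TaskDefinition


@dataclass(frozen=True)
class Coefficients:
    """Weights of the suitability criteria.

    ``ku``, ``ki``, ``kc`` weight usage, improvement and clinical scores in
    the GSS; ``w_primary`` and ``w_other`` weight the designated-subfunction
    and other-function deltas inside the improvement score.
    """

    ku: float = 1.0
    ki: float = 1.0
    kc: float = 1.0
    w_primary: float = 1.0
    w_other: float = 0.5

    def __post_init__(self) -> None:
        vals = (self.ku, self.ki, self.kc, self.w_primary, self.w_other)
        if any(v < 0 for v in vals):
            raise ValueError("coefficients must be non-negative")
        if self.ku == self.ki == self.kc == 0:
            raise ValueError("at least one of ku, ki, kc must be positive")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-task criterion scores, GSS and suitability quartile."""

    task_id: str
    usage: int
    improvement: float
    clinical: int
    gss: float
    suitability_quartile: int | None = None


def usage_score(
    task: TaskDefinition, cluster_log: Sequence[ExecutionRecord]
) -> int:
    """Usage criterion: 4 for the most-used quartile down to 1, 0 if unused.

    ``cluster_log`` must already be restricted to executions by patients in
    the target cluster.  Used tasks are ordered by descending execution
    count and split into 4 contiguous near-equal groups; tasks with equal
    counts all receive the best score any of them occupies.
    """
    counts = Counter(rec.task_id for rec in cluster_log)
    if counts[task.task_id] == 0:
        return 0
    # Deterministic order: descending count, ties by task id.
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    quartile = quartile_of(ordered)
    score_by_count: dict[int, int] = {}
    for tid in ordered:
        score = 5 - quartile[tid]
        c = counts[tid]
        score_by_count[c] = max(score_by_count.get(c, 0), score)
    return score_by_count[counts[task.task_id]]


def improvement_score(
    task: TaskDefinition,
    cluster_outcomes: Sequence[tuple[CognitiveProfile, CognitiveProfile, Iterable[str]]],
    coeff: Coefficients = Coefficients(),
) -> float:
    """Improvement criterion from cluster patients who executed the task.

    Each outcome is ``(pre, post, executed_task_ids)``.  Over executors,
    the mean drop in impairment on the task's designated subfunction
    (delta_primary) and the mean drop at function level on the two
    non-designated functions (delta_other) combine as
    ``w_primary*delta_primary + w_other*delta_other``, clamped to [0, 4].
    Returns 0 when no cluster patient executed the task.
    """
    primary_deltas: list[float] = []
    other_deltas: list[float] = []
    sub = task.subfunction
    own_fn = task.taxonomy.parent(sub)
    other_fns = [f for f in task.taxonomy.functions if f != own_fn]
    for pre, post, executed in cluster_outcomes:
        if task.task_id not in set(executed):
            continue
        primary_deltas.append(
            pre.subfunction_impairment[sub] - post.subfunction_impairment[sub]
        )
        pre_f, post_f = pre.function_impairment, post.function_impairment
        other_deltas.append(
            sum(pre_f[f] - post_f[f] for f in other_fns) / len(other_fns)
        )
    if not primary_deltas:
        return 0.0
    dp = sum(primary_deltas) / len(primary_deltas)
    do = sum(other_deltas) / len(other_deltas)
    return float(min(4.0, max(0.0, coeff.w_primary * dp + coeff.w_other * do)))


def clinical_score(profile: CognitiveProfile, task: TaskDefinition) -> int:
    """Combined clinical score IL&CC: sum over subfunctions of IL_s * CC_s."""
    if profile.taxonomy != task.taxonomy:
        raise ValueError("profile and task are over different taxonomies")
    return sum(
        profile.subfunction_impairment[s] * task.clinical_criteria[s]
        for s in task.taxonomy.subfunction_names
    )


def global_suitability(
    usage: int, improvement: float, clinical: int, coeff: Coefficients = Coefficients()
) -> float:
    """GSS = U*ku + I*ki + IL&CC*kc."""
    return usage * coeff.ku + improvement * coeff.ki + clinical * coeff.kc


def suitability_quartiles(scores: Sequence[ScoreBreakdown]) -> dict[str, int]:
    """Split tasks into SQ1..SQ4 by descending GSS (ties by ascending task id)."""
    if not scores:
        raise ValueError("cannot compute suitability quartiles of an empty catalog")
    ordered = sorted(scores, key=lambda b: (-b.gss, b.task_id))
    return quartile_of([b.task_id for b in ordered])


def score_catalog(
    profile: CognitiveProfile,
    catalog: Sequence[TaskDefinition],
    cluster_log: Sequence[ExecutionRecord] = (),
    cluster_outcomes: Sequence[tuple[CognitiveProfile, CognitiveProfile, Iterable[str]]] = (),
    coeff: Coefficients = Coefficients(),
) -> list[ScoreBreakdown]:
    """Score every catalog task for one patient and attach suitability quartiles."""
    partial = []
    for task in catalog:
        u = usage_score(task, cluster_log)
        i = improvement_score(task, cluster_outcomes, coeff)
        c = clinical_score(profile, task)
        partial.append(
            ScoreBreakdown(task.task_id, u, i, c, global_suitability(u, i, c, coeff))
        )
    sq = suitability_quartiles(partial)
    return [
        ScoreBreakdown(b.task_id, b.usage, b.improvement, b.clinical, b.gss, sq[b.task_id])
        for b in partial
    ]
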