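"""Session assembly and adaptive difficulty configuration.

Sessions are planned in blocks of ten one-hour sessions.  Tasks are drawn
cyclically from the suitability quartiles in the fixed pattern 3 from SQ1,
2 from SQ2, 2 from SQ3, 1 from SQ4 — rewarding the most suitable tasks
without discarding the rest — until the session's duration budget is
exhausted.

Each task's parameter space is enumerated into configurations, ordered by
total difficulty weight, and split into difficulty quartiles DQ1 (easiest)
.. DQ4 (hardest).  The quartile actually scheduled depends on the patient's
PRE impairment on the task's designated subfunction, adjusted between
blocks by the Mean Execution Result per Subfunction (MERS):

* MERS < 65 (infra-therapeutic): impairment + 1 — the patient needs easier tasks;
* 65 <= MERS <= 85 (therapeutic):  impairment - 1 — the patient is progressing;
* MERS > 85 (supra-therapeutic):  impairment - 2 — tasks are too easy.

The first planner version (v1) schedules a whole treatment upfront from the
PRE assessment alone; the second (v2) re-plans every block with the MERS
adjustment.  An execution scoring outside the therapeutic band 65-85 is
re-launched into the next open session one difficulty quartile easier
(infra) or harder (supra).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .profile import CognitiveProfile
from .quartiles import N_QUARTILES, quartile_of
from .tasks import ExecutionRecord, TaskDefinition

logger = logging.getLogger(__name__)

THERAPEUTIC_LOW = 65.0
THERAPEUTIC_HIGH = 85.0

#: Draw pattern over suitability quartiles within one 8-task cycle.
SQ_DRAW_PATTERN = (1, 1, 1, 2, 2, 3, 3, 4)


def classify_range(
    score: float,
    low: float = THERAPEUTIC_LOW,
    high: float = THERAPEUTIC_HIGH,
) -> str:
    """Classify a 0-100 execution score as infra / therapeutic / supra.

    Boundary scores (65 and 85 by default) are therapeutic, so the three
    ranges partition [0, 100].
    """
    if not 0 <= score <= 100:
        raise ValueError(f"score must be in [0, 100], got {score}")
    if score < low:
        return "infra"
    if score > high:
        return "supra"
    return "therapeutic"


@dataclass(frozen=True)
class DifficultyModel:
    """A task's enumerated parameter space split into difficulty quartiles.

    ``configurations`` are ordered ascending by total weight (ties broken by
    the parameter-value enumeration order); ``dq`` gives the 1-based
    difficulty quartile of each, DQ1 being the easiest.
    """

    task: TaskDefinition
    configurations: tuple[Mapping[str, str], ...]
    weights: tuple[int, ...]
    dq: tuple[int, ...]

    def configurations_in(self, quartile: int) -> list[Mapping[str, str]]:
        return [c for c, q in zip(self.configurations, self.dq) if q == quartile]

    def quartile_of_configuration(self, configuration: Mapping[str, str]) -> int:
        target = dict(configuration)
        for c, q in zip(self.configurations, self.dq):
            if dict(c) == target:
                return q
        raise KeyError(
            f"configuration {target} not in parameter space of task {self.task.task_id}"
        )


def build_difficulty_model(task: TaskDefinition) -> DifficultyModel:
    """Enumerate the cartesian parameter space and split it into DQ1..DQ4."""
    if not task.parameters:
        raise ValueError(f"task {task.task_id} has no parameters")
    names = [p.name for p in task.parameters]
    combos = list(itertools.product(*(range(len(p.values)) for p in task.parameters)))
    weighted = []
    for combo in combos:
        weight = sum(p.weights[i] for p, i in zip(task.parameters, combo))
        weighted.append((weight, combo))
    # itertools.product emits index tuples in lexicographic order already,
    # so a stable sort on weight keeps the lexicographic tie-break.
    weighted.sort(key=lambda wc: wc[0])
    configs = tuple(
        {name: p.values[i] for name, p, i in zip(names, task.parameters, combo)}
        for _, combo in weighted
    )
    weights = tuple(w for w, _ in weighted)
    dq_by_pos = quartile_of(range(len(configs)))
    return DifficultyModel(task, configs, weights, tuple(dq_by_pos[i] for i in range(len(configs))))


@dataclass(frozen=True)
class MersState:
    """Mean execution score per subfunction; a subfunction with no executions is absent."""

    means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, m in self.means.items():
            if not 0 <= m <= 100:
                raise ValueError(f"MERS for {sub!r} out of [0, 100]: {m}")

    def get(self, subfunction: str) -> float | None:
        return self.means.get(subfunction)


def compute_mers(
    log: Sequence[ExecutionRecord], designated: Mapping[str, str]
) -> MersState:
    """Average execution score per subfunction.

    ``designated`` maps task id -> designated subfunction.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in log:
        sub = designated[rec.task_id]
        sums[sub] = sums.get(sub, 0.0) + rec.score
        counts[sub] = counts.get(sub, 0) + 1
    return MersState({sub: sums[sub] / counts[sub] for sub in sums})


def adjusted_impairment(
    pre_value: int,
    mers: float | None,
    low: float = THERAPEUTIC_LOW,
    high: float = THERAPEUTIC_HIGH,
) -> int:
    """PRE impairment adjusted by running performance, clamped to 0..4."""
    if pre_value not in (0, 1, 2, 3, 4):
        raise ValueError(f"pre_value must be in 0..4, got {pre_value}")
    if mers is None:
        return pre_value
    if mers < low:
        adj = pre_value + 1
    elif mers > high:
        adj = pre_value - 2
    else:
        adj = pre_value - 1
    return max(0, min(4, adj))


def target_difficulty_quartile(adj_impairment: int) -> int:
    """Map adjusted impairment 0..4 to a difficulty quartile: severest -> easiest."""
    return max(1, min(N_QUARTILES, N_QUARTILES - adj_impairment))


def select_difficulty(
    model: DifficultyModel,
    adj_impairment: int,
    rng: np.random.Generator | int = 0,
) -> Mapping[str, str]:
    """Sample a configuration uniformly from the quartile matching the impairment.

    Small parameter spaces can leave upper quartiles empty; the nearest
    non-empty quartile is used then, preferring the easier side on ties.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    target = target_difficulty_quartile(adj_impairment)
    candidates = model.configurations_in(target)
    if not candidates:
        occupied = sorted(set(model.dq), key=lambda q: (abs(q - target), q))
        candidates = model.configurations_in(occupied[0])
    return candidates[rng.integers(len(candidates))]


@dataclass
class SessionPlan:
    """One planned session: ordered (task, configuration) entries within the duration cap."""

    session_index: int
    entries: list[tuple[TaskDefinition, Mapping[str, str], int]] = field(default_factory=list)
    session_minutes: float = 60.0

    @property
    def total_duration(self) -> float:
        return sum(task.duration_minutes for task, _, _ in self.entries)

    @property
    def task_ids(self) -> list[str]:
        return [task.task_id for task, _, _ in self.entries]

    def fits(self, task: TaskDefinition) -> bool:
        return (
            task.task_id not in self.task_ids
            and self.total_duration + task.duration_minutes <= self.session_minutes
        )


def assemble_block(
    sq: Mapping[str, int],
    catalog: Sequence[TaskDefinition],
    profile: CognitiveProfile,
    mers: MersState | None = None,
    version: str = "v2",
    block_size: int = 10,
    session_minutes: float = 60.0,
    first_session_index: int = 1,
    rng: np.random.Generator | int = 0,
) -> list[SessionPlan]:
    """Assemble one block of sessions from the suitability quartiles.

    Tasks are drawn cyclically 3 x SQ1, 2 x SQ2, 2 x SQ3, 1 x SQ4, sampled
    uniformly without replacement within a session (and with replacement
    across sessions).  A session closes when the drawn task no longer fits
    its duration budget; that task opens the next session so the draw cycle
    is never skipped.  A demanded quartile with no available task falls
    through to the next non-empty one.  Difficulty is configured from the
    patient's PRE impairment on the task's designated subfunction, adjusted
    by MERS when ``version == "v2"``.
    """
    if version not in ("v1", "v2"):
        raise ValueError(f"version must be 'v1' or 'v2', got {version!r}")
    if not catalog:
        raise ValueError("catalog is empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mers = mers if (mers is not None and version == "v2") else MersState()
    by_task = {t.task_id: t for t in catalog}
    by_quartile: dict[int, list[str]] = {q: [] for q in range(1, N_QUARTILES + 1)}
    for tid, q in sq.items():
        by_quartile[q].append(tid)
    for tids in by_quartile.values():
        tids.sort()
    difficulty = {t.task_id: build_difficulty_model(t) for t in catalog}

    pattern = itertools.cycle(SQ_DRAW_PATTERN)

    def draw(session: SessionPlan) -> TaskDefinition | None:
        q = next(pattern)
        for step in range(N_QUARTILES):
            quartile = (q - 1 + step) % N_QUARTILES + 1
            pool = [tid for tid in by_quartile[quartile] if tid not in session.task_ids]
            if pool:
                if step:
                    logger.info(
                        "quartile SQ%d exhausted; falling through to SQ%d", q, quartile
                    )
                return by_task[pool[rng.integers(len(pool))]]
        return None

    sessions: list[SessionPlan] = []
    carried: TaskDefinition | None = None
    for offset in range(block_size):
        session = SessionPlan(first_session_index + offset, session_minutes=session_minutes)
        oversized_skips = 0
        while oversized_skips <= len(catalog):
            if carried is not None and carried.task_id not in session.task_ids:
                task, carried = carried, None
            else:
                task = draw(session)
            if task is None:
                break
            if not session.fits(task):
                if session.entries:
                    carried = task  # opens the next session
                    break
                logger.warning(
                    "task %s (%.0f min) exceeds the session budget on its own; skipped",
                    task.task_id,
                    task.duration_minutes,
                )
                oversized_skips += 1
                continue
            pre = profile.subfunction_impairment[task.subfunction]
            adj = adjusted_impairment(pre, mers.get(task.subfunction))
            config = select_difficulty(difficulty[task.task_id], adj, rng)
            dq = difficulty[task.task_id].quartile_of_configuration(config)
            session.entries.append((task, config, dq))
        sessions.append(session)
    return sessions


def relaunch(
    record: ExecutionRecord,
    model: DifficultyModel,
    block: Sequence[SessionPlan],
    rng: np.random.Generator | int = 0,
) -> Sequence[SessionPlan]:
    """Re-queue an out-of-therapeutic-range execution at an adjusted difficulty.

    Infra-therapeutic scores re-queue the task one difficulty quartile
    easier, supra-therapeutic one harder (clamped to DQ1/DQ4), into the
    first later session with room for it; therapeutic scores leave the
    block unchanged.  Mutates and returns ``block``.
    """
    if record.range == "therapeutic":
        return block
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    step = -1 if record.range == "infra" else 1
    current = model.quartile_of_configuration(record.configuration)
    new_dq = max(1, min(N_QUARTILES, current + step))
    candidates = model.configurations_in(new_dq)
    if not candidates:  # tiny parameter spaces may leave a quartile empty
        occupied = sorted(set(model.dq), key=lambda q: (abs(q - new_dq), q))
        candidates = model.configurations_in(occupied[0])
        new_dq = occupied[0]
    config = candidates[rng.integers(len(candidates))]
    task = model.task
    for session in block:
        if session.session_index > record.session_index and session.fits(task):
            session.entries.append((task, config, new_dq))
            return block
    logger.warning(
        "no open session left in block to re-launch task %s", record.task_id
    )
    return block
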