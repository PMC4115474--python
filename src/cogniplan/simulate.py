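"""Synthetic cohorts, task catalogs and execution responses.

No open clinical dataset accompanies the planner, so this module generates
cohorts and execution behaviour with the statistical structure the planner
assumes, enabling a closed-loop comparison of planner versions:

* **Cohorts** are drawn from archetype impairment profiles (cluster means
  with Gaussian noise, rounded and clamped to the 0-4 scale), mimicking the
  clustered structure of real ABI cohorts; the generating archetype label is
  kept as hidden ground truth for evaluating cluster recovery.
* **Responses** follow a latent-ability logistic model: each patient holds
  an ability theta = (4 - impairment)/4 in [0, 1] per subfunction, and the
  expected score of executing a task at normalised difficulty d (total
  configuration weight / max weight) is

      E[score] = 100 * logistic(gamma * (theta - d) + log 3)

  so a difficulty exactly matching ability yields an expected score of 75,
  the middle of the therapeutic band.  Scores get additive Gaussian noise
  and are clamped to [0, 100].  Ability increases by a small increment
  delta after each therapeutic-range execution — encoding the premise that
  well-matched difficulty is what drives improvement — and the POST profile
  is read back from the final abilities by inverse banding.

``run_closed_loop`` alternates planning and simulated execution per
10-session block and summarises range fractions and the improvement rate,
re-creating the planner-version comparison on synthetic patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .profile import CognitiveProfile, improved
from .scheduler import classify_range
from .scoring import Coefficients, score_catalog
from .tasks import BINGO, ExecutionRecord, Parameter, TaskDefinition
from .taxonomy import ABI_TAXONOMY, Taxonomy


@dataclass(frozen=True)
class Archetype:
    """A cluster prototype: mean impairment vector and within-cluster SD."""

    means: tuple[float, ...]
    sd: float = 0.3

    def __post_init__(self) -> None:
        if any(not 0 <= m <= 4 for m in self.means):
            raise ValueError("archetype means must lie in [0, 4]")
        if self.sd <= 0:
            raise ValueError("archetype SD must be positive")


#: Default archetypes: a mildly and a severely impaired patient group.
DEFAULT_ARCHETYPES = (
    Archetype(means=(0.5,) * 11, sd=0.3),
    Archetype(means=(3.5,) * 11, sd=0.3),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    n_patients: int = 50
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    seed: int = 0
    age_range: tuple[float, float] = (18.0, 80.0)
    education_levels: tuple[str, ...] = ("primary", "secondary", "higher")
    taxonomy: Taxonomy = ABI_TAXONOMY


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    profile: CognitiveProfile
    archetype_index: int
    age: float
    education: str


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Draw a cohort of PRE profiles from the configured archetypes."""
    rng = np.random.default_rng(config.seed)
    cohort = []
    for i in range(config.n_patients):
        a = int(rng.integers(len(config.archetypes)))
        arch = config.archetypes[a]
        raw = rng.normal(arch.means, arch.sd)
        profile = CognitiveProfile.from_vector(np.clip(raw, 0, 4), config.taxonomy)
        cohort.append(
            SyntheticPatient(
                patient_id=f"sim{i:04d}",
                profile=profile,
                archetype_index=a,
                age=float(rng.uniform(*config.age_range)),
                education=str(rng.choice(config.education_levels)),
            )
        )
    return cohort


def synthetic_catalog(
    n_tasks: int = 24,
    seed: int = 0,
    taxonomy: Taxonomy = ABI_TAXONOMY,
    include_bingo: bool = True,
) -> list[TaskDefinition]:
    """A synthetic ABI task catalog (plus the real Bingo definition).

    Tasks rotate over the 11 subfunctions; each gets a clinical-criteria
    vector peaked on its designated subfunction, 2-3 difficulty parameters
    and a nominal duration of 6-10 minutes.
    """
    rng = np.random.default_rng(seed)
    tasks: list[TaskDefinition] = [BINGO] if include_bingo else []
    i = 0
    while len(tasks) < n_tasks:
        sub = taxonomy.subfunction_names[i % taxonomy.n_subfunctions]
        cc = {s: 0 for s in taxonomy.subfunction_names}
        cc[sub] = int(rng.integers(2, 5))
        for other in rng.choice(
            [s for s in taxonomy.subfunction_names if s != sub], size=2, replace=False
        ):
            cc[other] = int(rng.integers(0, 3))
        n_params = int(rng.integers(2, 4))
        params = []
        for j in range(n_params):
            n_vals = int(rng.integers(2, 5))
            params.append(
                Parameter(
                    name=f"p{j}",
                    values=tuple(f"v{v}" for v in range(n_vals)),
                    weights=tuple(range(n_vals)),
                )
            )
        params = tuple(params)
        tasks.append(
            TaskDefinition(
                task_id=f"task{i:03d}",
                name=f"Synthetic task {i}",
                subfunction=sub,
                clinical_criteria=cc,
                parameters=params,
                duration_minutes=float(rng.integers(6, 11)),
            )
        )
        i += 1
    return tasks


@dataclass
class ResponseModel:
    """Latent-ability logistic response model.

    ``gamma`` is the logistic slope on the ability-difficulty gap,
    ``noise_sd`` the additive score noise (points), ``learning_delta`` the
    ability increment applied after a therapeutic-range execution, and
    ``offset = log 3`` centres a matched execution at an expected score of
    75 (mid-therapeutic).
    """

    gamma: float = 5.0
    noise_sd: float = 8.0
    learning_delta: float = 0.05
    offset: float = float(np.log(3.0))

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def expected_score(self, theta: float, difficulty: float) -> float:
        z = self.gamma * (theta - difficulty) + self.offset
        return 100.0 / (1.0 + np.exp(-z))


class PatientState:
    """Mutable per-patient simulation state: latent ability per subfunction."""

    def __init__(self, patient: SyntheticPatient):
        self.patient = patient
        self.theta = {
            s: (4 - v) / 4
            for s, v in patient.profile.subfunction_impairment.items()
        }

    def post_profile(self) -> CognitiveProfile:
        """Read the POST profile back from abilities by inverse banding."""
        taxonomy = self.patient.profile.taxonomy
        vec = [4 * (1 - self.theta[s]) for s in taxonomy.subfunction_names]
        return CognitiveProfile.from_vector(vec, taxonomy)


def simulate_execution(
    state: PatientState,
    task: TaskDefinition,
    configuration: Mapping[str, str],
    response: ResponseModel,
    rng: np.random.Generator,
    session_index: int = 0,
) -> ExecutionRecord:
    """Execute one configured task, update ability, and return the record."""
    weight = task.configuration_weight(configuration)
    difficulty = weight / task.max_weight if task.max_weight > 0 else 0.0
    theta = state.theta[task.subfunction]
    expected = response.expected_score(theta, difficulty)
    score = float(np.clip(expected + rng.normal(0.0, response.noise_sd), 0.0, 100.0))
    band = classify_range(score)
    if band == "therapeutic":
        state.theta[task.subfunction] = min(1.0, theta + response.learning_delta)
    return ExecutionRecord(
        patient_id=state.patient.patient_id,
        task_id=task.task_id,
        session_index=session_index,
        configuration=dict(configuration),
        score=score,
        range=band,
    )


@dataclass
class ClosedLoopResult:
    """Outcome of one closed-loop run: log, POST profiles and summary."""

    log: list[ExecutionRecord]
    pre_profiles: dict[str, CognitiveProfile]
    post_profiles: dict[str, CognitiveProfile]
    summary: dict[str, float]


def run_closed_loop(
    cohort: Sequence[SyntheticPatient],
    catalog: Sequence[TaskDefinition],
    version: str = "v2",
    n_blocks: int = 3,
    response: ResponseModel | None = None,
    seed: int = 0,
    coeff: Coefficients = Coefficients(),
    block_size: int = 10,
    session_minutes: float = 60.0,
) -> ClosedLoopResult:
    """Alternate planning and simulated execution for a whole cohort.

    v2 re-plans each 10-session block with the MERS adjustment; v1 plans
    the entire treatment upfront from the PRE assessment alone.  Suitability
    scoring uses the clinical criterion only (no shared usage history is
    simulated across patients); the summary reports the infra / therapeutic
    / supra fractions and the fraction of improved patients.
    """
    from .scheduler import MersState, assemble_block, compute_mers

    response = response or ResponseModel()
    designated = {t.task_id: t.subfunction for t in catalog}
    log: list[ExecutionRecord] = []
    post_profiles: dict[str, CognitiveProfile] = {}
    for p_index, patient in enumerate(cohort):
        rng = np.random.default_rng([seed, p_index])
        state = PatientState(patient)
        breakdown = score_catalog(patient.profile, catalog, coeff=coeff)
        sq = {b.task_id: b.suitability_quartile for b in breakdown}
        patient_log: list[ExecutionRecord] = []

        if version == "v1":
            blocks = [
                assemble_block(
                    sq, catalog, patient.profile, mers=None, version="v1",
                    block_size=block_size * n_blocks,
                    session_minutes=session_minutes, rng=rng,
                )
            ]
        else:
            blocks = None  # planned lazily, block by block

        for b in range(n_blocks):
            if version == "v2":
                mers = compute_mers(patient_log, designated) if patient_log else MersState()
                sessions = assemble_block(
                    sq, catalog, patient.profile, mers=mers, version="v2",
                    block_size=block_size, session_minutes=session_minutes,
                    first_session_index=b * block_size + 1, rng=rng,
                )
            else:
                sessions = blocks[0][b * block_size : (b + 1) * block_size]
            for session in sessions:
                for task, config, _dq in session.entries:
                    patient_log.append(
                        simulate_execution(
                            state, task, config, response, rng, session.session_index
                        )
                    )
        log.extend(patient_log)
        post_profiles[patient.patient_id] = state.post_profile()

    pre_profiles = {p.patient_id: p.profile for p in cohort}
    summary = summarize_outcomes(log, pre_profiles, post_profiles)
    return ClosedLoopResult(log, pre_profiles, post_profiles, summary)


def summarize_outcomes(
    log: Sequence[ExecutionRecord],
    pre_profiles: Mapping[str, CognitiveProfile],
    post_profiles: Mapping[str, CognitiveProfile],
) -> dict[str, float]:
    """Range fractions over the log and the improved-patient fraction."""
    if not log:
        raise ValueError("execution log is empty")
    n = len(log)
    fractions = {
        r: sum(1 for rec in log if rec.range == r) / n
        for r in ("infra", "therapeutic", "supra")
    }
    ids = sorted(pre_profiles)
    if set(ids) != set(post_profiles):
        raise ValueError("PRE and POST profile ids do not match")
    improved_n = sum(1 for pid in ids if improved(pre_profiles[pid], post_profiles[pid]))
    return {
        "n_executions": float(n),
        "frac_infra": fractions["infra"],
        "frac_therapeutic": fractions["therapeutic"],
        "frac_supra": fractions["supra"],
        "improvement_rate": improved_n / len(ids) if ids else 0.0,
    }
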