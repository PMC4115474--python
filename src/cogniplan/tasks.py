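"""Rehabilitation task definitions and execution records.

Each computerized task targets one cognitive subfunction, carries a
clinician-defined *clinical criteria* vector rating how well it treats each
of the 11 subfunctions (0-4), and exposes a small parameter space; every
parameter value has an integer difficulty weight (0 = easiest value), so a
configuration's total weight orders the parameter space by difficulty.

The module also ships the Bingo task — a sustained-attention exercise in
which the patient clicks numbers appearing on a bingo card — whose parameter
space (matrix dimension x presentation time x level, 3 x 5 x 2 = 30
configurations) and clinical criteria (sustained 4, selective 2, divided 1)
are the package's worked example.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .taxonomy import ABI_TAXONOMY, Taxonomy

RANGES = ("infra", "therapeutic", "supra")


@dataclass(frozen=True)
class Parameter:
    """One task input parameter: ordered values with per-value difficulty weights."""

    name: str
    values: tuple[str, ...]
    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"parameter {self.name!r} has no values")
        if len(self.values) != len(self.weights):
            raise ValueError(f"parameter {self.name!r}: values/weights length mismatch")
        if any(w < 0 or w != int(w) for w in self.weights):
            raise ValueError(f"parameter {self.name!r}: weights must be non-negative integers")
        if min(self.weights) != 0:
            raise ValueError(f"parameter {self.name!r}: easiest value must have weight 0")

    def weight_of(self, value: str) -> int:
        try:
            return self.weights[self.values.index(value)]
        except ValueError as exc:
            raise KeyError(f"parameter {self.name!r} has no value {value!r}") from exc


@dataclass(frozen=True)
class TaskDefinition:
    """A rehabilitation task in the catalog."""

    task_id: str
    name: str
    subfunction: str
    clinical_criteria: Mapping[str, int]
    parameters: tuple[Parameter, ...]
    duration_minutes: float
    taxonomy: Taxonomy = ABI_TAXONOMY

    def __post_init__(self) -> None:
        names = set(self.taxonomy.subfunction_names)
        if self.subfunction not in names:
            raise ValueError(f"task {self.task_id}: unknown subfunction {self.subfunction!r}")
        if set(self.clinical_criteria) != names:
            raise ValueError(f"task {self.task_id}: clinical criteria keys do not match taxonomy")
        for sub, v in self.clinical_criteria.items():
            if not (isinstance(v, int) and 0 <= v <= 4):
                raise ValueError(
                    f"task {self.task_id}: clinical criterion for {sub!r} must be an "
                    f"integer in 0..4, got {v!r}"
                )
        if self.clinical_criteria[self.subfunction] <= 0:
            raise ValueError(
                f"task {self.task_id}: designated subfunction must have a positive criterion"
            )
        if self.duration_minutes <= 0:
            raise ValueError(f"task {self.task_id}: duration must be positive")

    def cc_vector(self) -> tuple[int, ...]:
        return tuple(self.clinical_criteria[s] for s in self.taxonomy.subfunction_names)

    def configuration_weight(self, configuration: Mapping[str, str]) -> int:
        """Total difficulty weight of one parameter-value configuration."""
        if set(configuration) != {p.name for p in self.parameters}:
            raise KeyError(
                f"task {self.task_id}: configuration keys {sorted(configuration)} do not "
                f"match parameters {[p.name for p in self.parameters]}"
            )
        return sum(p.weight_of(configuration[p.name]) for p in self.parameters)

    @property
    def max_weight(self) -> int:
        return sum(max(p.weights) for p in self.parameters)


@dataclass(frozen=True)
class ExecutionRecord:
    """One execution of a configured task, with its 0-100 score and range."""

    patient_id: str
    task_id: str
    session_index: int
    configuration: Mapping[str, str]
    score: float
    range: str

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 100:
            raise ValueError(f"score must be in [0, 100], got {self.score}")
        if self.range not in RANGES:
            raise ValueError(f"range must be one of {RANGES}, got {self.range!r}")


def _cc(**nonzero: int) -> dict[str, int]:
    cc = {s: 0 for s in ABI_TAXONOMY.subfunction_names}
    cc.update(nonzero)
    return cc


#: The Bingo task, exactly as specified clinically: three parameters
#: (3 matrix dimensions x 5 presentation times x 2 levels) and clinical
#: criteria 4/2/1 on sustained/selective/divided attention.
BINGO = TaskDefinition(
    task_id="bingo",
    name="Bingo",
    subfunction="sustained",
    clinical_criteria=_cc(sustained=4, selective=2, divided=1),
    parameters=(
        Parameter("dimension", ("4x4", "5x5", "6x6"), (0, 1, 2)),
        Parameter("presentation_time", ("4", "3.5", "3", "2.5", "2"), (0, 1, 2, 3, 4)),
        Parameter("level", ("ordered", "in disorder"), (0, 1)),
    ),
    duration_minutes=8.0,
)
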