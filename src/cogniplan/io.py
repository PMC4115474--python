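"""File formats: cohort CSV, task-catalog JSON, execution-log CSV, run config.

All tabular data travels as CSV (via pandas) and all structured objects as
JSON, so every artifact is human-inspectable and diff-friendly.  Readers
validate invariants and raise errors naming the offending field, task or
row; every writer emits files its reader accepts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .profile import CognitiveProfile
from .scheduler import classify_range
from .tasks import ExecutionRecord, Parameter, TaskDefinition
from .taxonomy import ABI_TAXONOMY, Taxonomy


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the CLI pipeline stages."""

    ku: float = 1.0
    ki: float = 1.0
    kc: float = 1.0
    w_primary: float = 1.0
    w_other: float = 0.5
    therapeutic_low: float = 65.0
    therapeutic_high: float = 85.0
    session_minutes: float = 60.0
    block_size: int = 10
    version: str = "v2"
    relaunch_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.therapeutic_low < self.therapeutic_high < 100):
            raise ValueError(
                "need 0 < therapeutic_low < therapeutic_high < 100, got "
                f"{self.therapeutic_low}, {self.therapeutic_high}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


# -- task catalog -----------------------------------------------------------

def read_task_catalog(path: str | Path, taxonomy: Taxonomy = ABI_TAXONOMY) -> list[TaskDefinition]:
    """Read a JSON array of task definitions, validating every invariant."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: task catalog must be a non-empty JSON array")
    tasks = []
    for entry in raw:
        tid = entry.get("task_id", "<missing task_id>")
        try:
            params = tuple(
                Parameter(p["name"], tuple(p["values"]), tuple(p["weights"]))
                for p in entry["parameters"]
            )
            tasks.append(
                TaskDefinition(
                    task_id=entry["task_id"],
                    name=entry.get("name", entry["task_id"]),
                    subfunction=entry["subfunction"],
                    clinical_criteria={
                        k: int(v) for k, v in entry["clinical_criteria"].items()
                    },
                    parameters=params,
                    duration_minutes=float(entry["duration_minutes"]),
                    taxonomy=taxonomy,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"task {tid}: {exc}") from exc
    return tasks


def write_task_catalog(tasks: Sequence[TaskDefinition], path: str | Path) -> None:
    out = [
        {
            "task_id": t.task_id,
            "name": t.name,
            "subfunction": t.subfunction,
            "clinical_criteria": dict(t.clinical_criteria),
            "parameters": [
                {"name": p.name, "values": list(p.values), "weights": list(p.weights)}
                for p in t.parameters
            ],
            "duration_minutes": t.duration_minutes,
        }
        for t in tasks
    ]
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


# -- cohort CSV -------------------------------------------------------------

COHORT_META_COLUMNS = ("patient_id", "timepoint", "age", "education")


def write_cohort(
    rows: Sequence[tuple[str, str, float, str, CognitiveProfile]], path: str | Path
) -> None:
    """Write (patient_id, timepoint, age, education, profile) rows to CSV."""
    records = []
    for pid, timepoint, age, education, profile in rows:
        rec = {"patient_id": pid, "timepoint": timepoint, "age": age, "education": education}
        rec.update(profile.subfunction_impairment)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_cohort(
    path: str | Path, taxonomy: Taxonomy = ABI_TAXONOMY
) -> list[tuple[str, str, float, str, CognitiveProfile]]:
    """Read a cohort CSV of pre-banded 0-4 impairment vectors."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_META_COLUMNS + taxonomy.subfunction_names if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rows = []
    for i, row in df.iterrows():
        try:
            profile = CognitiveProfile(
                {s: int(row[s]) for s in taxonomy.subfunction_names}, taxonomy
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
        timepoint = str(row["timepoint"]).upper()
        if timepoint not in ("PRE", "POST"):
            raise ValueError(f"{path} row {i}: timepoint must be PRE or POST")
        rows.append(
            (str(row["patient_id"]), timepoint, float(row["age"]), str(row["education"]), profile)
        )
    return rows


# -- execution log CSV ------------------------------------------------------

LOG_COLUMNS = ("patient_id", "task_id", "session_index", "configuration", "score", "range")


def write_execution_log(log: Sequence[ExecutionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in log],
            "task_id": [r.task_id for r in log],
            "session_index": [r.session_index for r in log],
            "configuration": [json.dumps(dict(r.configuration), sort_keys=True) for r in log],
            # repr round-trips the float exactly through the CSV
            "score": [repr(float(r.score)) for r in log],
            "range": [r.range for r in log],
        }
    )
    df.to_csv(path, index=False)


def read_execution_log(path: str | Path) -> list[ExecutionRecord]:
    """Read an execution log CSV, re-checking the score/range consistency."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        score = float(row["score"])
        if not 0 <= score <= 100:
            raise ValueError(f"{path} row {i}: score {score} out of [0, 100]")
        expected = classify_range(score)
        if str(row["range"]) != expected:
            raise ValueError(
                f"{path} row {i}: range {row['range']!r} inconsistent with "
                f"score {score} (expected {expected!r})"
            )
        records.append(
            ExecutionRecord(
                patient_id=str(row["patient_id"]),
                task_id=str(row["task_id"]),
                session_index=int(row["session_index"]),
                configuration=json.loads(row["configuration"]),
                score=score,
                range=str(row["range"]),
            )
        )
    return records


# -- block plan CSV ---------------------------------------------------------

def write_block_plan(patient_id: str, sessions, path: str | Path) -> None:
    """Write assembled sessions as a flat CSV (one row per scheduled task)."""
    rows = []
    for session in sessions:
        for position, (task, config, dq) in enumerate(session.entries, start=1):
            rec = {
                "patient_id": patient_id,
                "session_index": session.session_index,
                "position": position,
                "task_id": task.task_id,
                "dq": dq,
                "duration_minutes": task.duration_minutes,
            }
            rec.update({f"param_{k}": v for k, v in config.items()})
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)
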