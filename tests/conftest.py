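import pytest

from cogniplan import (
    ABI_TAXONOMY,
    BINGO,
    CognitiveProfile,
    Parameter,
    TaskDefinition,
)

#: Worked-example impairment levels, in taxonomy order: sustained 3,
#: selective 2, divided 3, visual 2, verbal 1, working 3, scheduling 1,
#: inhibition 0, flexibility 1, sequencing 2, categorization 0.
WORKED_EXAMPLE_LEVELS = (3, 2, 3, 2, 1, 3, 1, 0, 1, 2, 0)


@pytest.fixture
def worked_example_profile() -> CognitiveProfile:
    return CognitiveProfile(
        dict(zip(ABI_TAXONOMY.subfunction_names, WORKED_EXAMPLE_LEVELS))
    )


@pytest.fixture
def uniform_profile() -> CognitiveProfile:
    """All subfunctions at impairment level 1."""
    return CognitiveProfile({s: 1 for s in ABI_TAXONOMY.subfunction_names})


def make_task(
    task_id: str,
    subfunction: str = "sustained",
    cc_overrides: dict | None = None,
    n_values: int = 4,
    duration: float = 7.5,
) -> TaskDefinition:
    cc = {s: 0 for s in ABI_TAXONOMY.subfunction_names}
    cc[subfunction] = 1
    if cc_overrides:
        cc.update(cc_overrides)
    return TaskDefinition(
        task_id=task_id,
        name=task_id,
        subfunction=subfunction,
        clinical_criteria=cc,
        parameters=(
            Parameter("level", tuple(f"v{i}" for i in range(n_values)), tuple(range(n_values))),
        ),
        duration_minutes=duration,
    )


@pytest.fixture
def distinct_gss_catalog() -> list[TaskDefinition]:
    """12 tasks whose clinical scores (hence GSS) are all distinct for an
    all-ones profile: task i has total clinical-criteria mass i + 1."""
    tasks = []
    subs = ABI_TAXONOMY.subfunction_names
    for i in range(12):
        designated = subs[i % len(subs)]
        total = i + 1
        cc = {}
        cc[designated] = min(4, total)
        remainder = total - cc[designated]
        j = 0
        while remainder > 0:
            other = subs[(i + 1 + j) % len(subs)]
            if other != designated:
                take = min(4, remainder)
                cc[other] = cc.get(other, 0) + take
                remainder -= take
            j += 1
        tasks.append(make_task(f"t{i:02d}", designated, cc, duration=7.5))
    return tasks


@pytest.fixture
def bingo() -> TaskDefinition:
    return BINGO
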