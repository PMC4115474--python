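"""Cognitive impairment profiles.

A patient's neuropsychological assessment is normalised into a *cognitive
profile*: an integer impairment level 0 (normality) .. 4 (very severe
impairment) for each of the 11 subfunctions, plus an aggregate level per
cognitive function.  Profiles drive clustering, clinical scoring and
difficulty selection, and the PRE/POST pair of profiles defines whether a
treatment improved the patient.

Normalisation converts each raw test item to a z-score against an
age-band/education-stratified normative mean and SD, averages the z-scores of
the items mapped to each subfunction, and bands the mean z into 0-4:

    z > -1        -> 0
    -2 < z <= -1  -> 1
    -3 < z <= -2  -> 2
    -4 < z <= -3  -> 3
    z <= -4       -> 4

i.e. one severity level per standard deviation below the norm.  Function
aggregates are the arithmetic mean of the subfunction levels, rounded
half-up.  Cohorts may also supply pre-banded 0-4 vectors directly, since
clinical normative tables are typically proprietary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .taxonomy import ABI_TAXONOMY, Taxonomy

MAX_IMPAIRMENT = 4


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def band_z(z: float) -> int:
    """Band a z-score into an impairment level 0-4 (1 level per SD below norm)."""
    if z > -1:
        return 0
    if z > -2:
        return 1
    if z > -3:
        return 2
    if z > -4:
        return 3
    return 4


@dataclass(frozen=True)
class CognitiveProfile:
    """Impairment levels per subfunction (0-4) with function aggregates.

    ``subfunction_impairment`` maps each of the 11 subfunction names to an
    integer in 0..4; ``function_impairment`` holds the per-function mean
    rounded half-up.
    """

    subfunction_impairment: Mapping[str, int]
    taxonomy: Taxonomy = ABI_TAXONOMY

    def __post_init__(self) -> None:
        names = set(self.taxonomy.subfunction_names)
        got = set(self.subfunction_impairment)
        if got != names:
            raise ValueError(f"profile keys {sorted(got ^ names)} do not match taxonomy")
        for name, v in self.subfunction_impairment.items():
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= MAX_IMPAIRMENT):
                raise ValueError(f"impairment for {name!r} must be an integer in 0..4, got {v!r}")

    @property
    def function_impairment(self) -> dict[str, int]:
        out = {}
        for fn in self.taxonomy.functions:
            vals = [self.subfunction_impairment[s] for s in self.taxonomy.children(fn)]
            out[fn] = _round_half_up(sum(vals) / len(vals))
        return out

    def as_vector(self) -> np.ndarray:
        """Impairment levels in taxonomy order, as floats (for clustering)."""
        return np.array(
            [float(self.subfunction_impairment[s]) for s in self.taxonomy.subfunction_names]
        )

    @classmethod
    def from_vector(cls, values: Sequence[float], taxonomy: Taxonomy = ABI_TAXONOMY) -> "CognitiveProfile":
        if len(values) != taxonomy.n_subfunctions:
            raise ValueError(
                f"expected {taxonomy.n_subfunctions} values, got {len(values)}"
            )
        banded = {
            name: int(min(MAX_IMPAIRMENT, max(0, _round_half_up(float(v)))))
            for name, v in zip(taxonomy.subfunction_names, values)
        }
        return cls(banded, taxonomy)


@dataclass(frozen=True)
class RawAssessment:
    """One patient's raw neuropsychological assessment.

    ``items`` holds ``(test_item_id, raw_score)`` pairs; the normative map
    translates item ids to subfunctions and raw scores to z-scores.
    """

    patient_id: str
    age: float
    education: str
    items: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class NormativeMap:
    """Item->subfunction mapping and stratified normative statistics.

    ``item_subfunction`` maps a test item id to its subfunction.  ``norms``
    maps item id -> age band label -> education level -> (mean, sd).
    ``age_bands`` maps an age band label to its (low, high] bounds in years.
    """

    item_subfunction: Mapping[str, str]
    norms: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]]
    age_bands: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for item, bands in self.norms.items():
            for band, by_edu in bands.items():
                for edu, (mean, sd) in by_edu.items():
                    if sd <= 0:
                        raise ValueError(
                            f"normative SD must be positive: item {item!r}, "
                            f"age band {band!r}, education {edu!r}"
                        )

    def age_band(self, age: float) -> str:
        for label, (lo, hi) in self.age_bands.items():
            if lo < age <= hi:
                return label
        raise KeyError(f"no age band covers age {age}")

    def z_score(self, item_id: str, raw: float, age: float, education: str) -> float:
        try:
            by_edu = self.norms[item_id][self.age_band(age)]
            mean, sd = by_edu[education]
        except KeyError as exc:
            raise KeyError(
                f"no normative stratum for item {item_id!r} "
                f"(age {age}, education {education!r})"
            ) from exc
        return (raw - mean) / sd


def normalize_assessment(
    raw: RawAssessment, norms: NormativeMap, taxonomy: Taxonomy = ABI_TAXONOMY
) -> CognitiveProfile:
    """Normalise raw test items into a 0-4 cognitive profile.

    Item scores are z-scored against the patient's age/education stratum,
    averaged per subfunction, and banded one severity level per SD below the
    normative mean.  Raises ``KeyError`` for an item without a stratum and
    ``ValueError`` for a subfunction with no mapped items.
    """
    per_sub: dict[str, list[float]] = {s: [] for s in taxonomy.subfunction_names}
    for item_id, raw_score in raw.items:
        if item_id not in norms.item_subfunction:
            raise KeyError(f"item {item_id!r} has no subfunction mapping")
        sub = norms.item_subfunction[item_id]
        if sub not in per_sub:
            raise KeyError(f"item {item_id!r} maps to unknown subfunction {sub!r}")
        per_sub[sub].append(norms.z_score(item_id, raw_score, raw.age, raw.education))
    missing = [s for s, zs in per_sub.items() if not zs]
    if missing:
        raise ValueError(f"no assessment items for subfunctions: {missing}")
    levels = {s: band_z(float(np.mean(zs))) for s, zs in per_sub.items()}
    return CognitiveProfile(levels, taxonomy)


def improved(pre: CognitiveProfile, post: CognitiveProfile) -> bool:
    """PRE -> POST improvement criterion.

    True iff at least one function-level impairment strictly decreases and
    none increases.
    """
    if pre.taxonomy != post.taxonomy:
        raise ValueError("profiles are over different taxonomies")
    pre_f = pre.function_impairment
    post_f = post.function_impairment
    if any(post_f[f] > pre_f[f] for f in pre.taxonomy.functions):
        return False
    return any(post_f[f] < pre_f[f] for f in pre.taxonomy.functions)
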