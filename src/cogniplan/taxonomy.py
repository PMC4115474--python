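"""Cognitive function/subfunction taxonomy.

Rehabilitation content for acquired brain injury (ABI) is organised around
three cognitive functions (attention, memory, executive functions) refined
into eleven treatable subfunctions.  Every task in the catalog targets one
subfunction, and patient impairment profiles are vectors over the eleven
subfunctions.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Taxonomy:
    """Ordered cognitive functions and their subfunctions.

    ``subfunctions`` is an ordered list of ``(subfunction, parent_function)``
    pairs; the order defines the coordinate order of every impairment vector
    in the package.
    """

    functions: tuple[str, ...]
    subfunctions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        parents = {parent for _, parent in self.subfunctions}
        if not parents <= set(self.functions):
            raise ValueError(
                f"subfunction parents {sorted(parents - set(self.functions))} "
                "are not declared functions"
            )

    @property
    def subfunction_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.subfunctions)

    @property
    def n_subfunctions(self) -> int:
        return len(self.subfunctions)

    def parent(self, subfunction: str) -> str:
        for name, parent in self.subfunctions:
            if name == subfunction:
                return parent
        raise KeyError(f"unknown subfunction {subfunction!r}")

    def children(self, function: str) -> tuple[str, ...]:
        if function not in self.functions:
            raise KeyError(f"unknown function {function!r}")
        return tuple(name for name, parent in self.subfunctions if parent == function)

    def index(self, subfunction: str) -> int:
        return self.subfunction_names.index(subfunction)


#: The standard ABI taxonomy: 3 functions, 11 subfunctions.
ABI_TAXONOMY = Taxonomy(
    functions=("attention", "memory", "executive"),
    subfunctions=(
        ("sustained", "attention"),
        ("selective", "attention"),
        ("divided", "attention"),
        ("visual", "memory"),
        ("verbal", "memory"),
        ("working", "memory"),
        ("scheduling", "executive"),
        ("inhibition", "executive"),
        ("flexibility", "executive"),
        ("sequencing", "executive"),
        ("categorization", "executive"),
    ),
)
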