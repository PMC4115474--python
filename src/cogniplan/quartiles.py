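"""Contiguous near-equal quartile splitting.

Suitability, usage and difficulty ratings all rely on the same primitive:
order items, then cut the ordered list into 4 contiguous groups whose sizes
differ by at most one, with the remainder going to the earlier groups
(e.g. 95 items -> 24, 24, 24, 23).
"""

from __future__ import annotations

from typing import Sequence, TypeVar

T = TypeVar("T")

N_QUARTILES = 4


def group_sizes(n: int, k: int = N_QUARTILES) -> list[int]:
    """Sizes of ``k`` contiguous near-equal groups over ``n`` items.

    Earlier groups absorb the remainder, so sizes are non-increasing and
    differ by at most 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def split_ordered(items: Sequence[T], k: int = N_QUARTILES) -> list[list[T]]:
    """Split an already-ordered sequence into ``k`` contiguous near-equal groups."""
    sizes = group_sizes(len(items), k)
    out: list[list[T]] = []
    start = 0
    for size in sizes:
        out.append(list(items[start : start + size]))
        start += size
    return out


def quartile_of(items: Sequence[T], k: int = N_QUARTILES) -> dict[T, int]:
    """Map each item of an ordered sequence to its 1-based group index."""
    mapping: dict[T, int] = {}
    for q, group in enumerate(split_ordered(items, k), start=1):
        for item in group:
            mapping[item] = q
    return mapping
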