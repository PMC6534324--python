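"""Fragmentation life cycles as integer partitions.

A life cycle is fixed by the critical group size M at which a group
fragments and by the sizes of the offspring groups it fragments into —
an integer partition of M with at least two parts (e.g. "2+1+1" for a
four-cell group splitting into one bicellular and two unicellular
offspring).  With two cell phenotypes, each offspring group is born in
one of finitely many (size, composition) states, the newborn types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "LifeCycle",
    "NewbornType",
    "enumerate_lifecycles",
    "newborn_types",
]


@dataclass(frozen=True)
class NewbornType:
    """An offspring group state at birth: ``size`` cells, ``n_A`` of type A."""

    size: int
    n_A: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"newborn size must be >= 1, got {self.size}")
        if not 0 <= self.n_A <= self.size:
            raise ValueError(
                f"n_A must lie in [0, size], got n_A={self.n_A}, size={self.size}")

    @property
    def n_B(self) -> int:
        return self.size - self.n_A

    @property
    def label(self) -> str:
        return f"{self.size}c{self.n_A}A"


@dataclass(frozen=True, init=False)
class LifeCycle:
    """A fragmentation mode: a partition of the critical size M.

    Parts are stored in canonical non-increasing order, so
    ``LifeCycle((2, 3, 2))`` and ``LifeCycle((3, 2, 2))`` are the same
    object value.  At least two parts are required — fragmentation always
    produces two or more offspring groups, so no part can equal M.
    """

    parts: tuple[int, ...]

    def __init__(self, parts) -> None:
        parts = tuple(sorted((int(p) for p in parts), reverse=True))
        if len(parts) < 2:
            raise ValueError(f"a life cycle needs at least 2 parts, got {parts}")
        if any(p < 1 for p in parts):
            raise ValueError(f"all parts must be >= 1, got {parts}")
        object.__setattr__(self, "parts", parts)

    @property
    def M(self) -> int:
        """Critical size: the group fragments immediately on reaching M cells."""
        return sum(self.parts)

    @property
    def name(self) -> str:
        """Canonical '+'-joined name, e.g. ``"4+3"`` or ``"2+1+1"``."""
        return "+".join(str(p) for p in self.parts)

    @classmethod
    def from_name(cls, name: str) -> "LifeCycle":
        """Parse a '+'-joined name such as ``"2+1+1"``."""
        try:
            parts = tuple(int(tok) for tok in name.split("+"))
        except ValueError:
            raise ValueError(f"malformed life-cycle name {name!r}") from None
        return cls(parts)

    def __str__(self) -> str:
        return self.name


def _partitions(n: int, max_part: int | None = None) -> Iterator[tuple[int, ...]]:
    """All partitions of n in non-increasing order, largest part first."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def enumerate_lifecycles(max_M: int) -> list[LifeCycle]:
    """All life cycles with critical size 2..max_M, deterministically ordered.

    For each M the single-part partition (M) is excluded (a group must
    split into >= 2 offspring), leaving p(M) - 1 life cycles; ordering is
    by M, then reverse-lexicographic on the canonical parts, so e.g.
    max_M=4 yields [1+1, 2+1, 1+1+1, 3+1, 2+2, 2+1+1, 1+1+1+1].
    """
    if max_M < 2:
        raise ValueError(f"max_M must be >= 2, got {max_M}")
    out: list[LifeCycle] = []
    for M in range(2, max_M + 1):
        for parts in _partitions(M):
            if len(parts) >= 2:
                out.append(LifeCycle(parts))
    return out


def newborn_types(lc: LifeCycle) -> tuple[NewbornType, ...]:
    """The S newborn (size, composition) states a life cycle can produce.

    For each distinct part size s there are s + 1 compositions
    (n_A = 0..s); equal-sized parts contribute the same types once.
    Ordered by size ascending, then n_A descending.
    """
    types: list[NewbornType] = []
    for s in sorted(set(lc.parts)):
        for n_A in range(s, -1, -1):
            types.append(NewbornType(size=s, n_A=n_A))
    return tuple(types)
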