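"""Single-step kernels of the group-growth model.

A group of i A-cells and j B-cells grows one cell at a time.  Payoffs
from the 2x2 game set, to first order in the selection strength w, both
which cell divides (cell-level selection) and how long the group waits
between divisions (group-level selection).  At division each daughter
independently switches phenotype with probability m.  On reaching the
critical size M the group immediately fragments, its cells randomly
assigned to the offspring groups of the life cycle.

Conventions
-----------
* Average payoffs exclude self-interaction by default: an A-cell in an
  (i, j) group averages over its i + j - 1 partners, and a solitary cell
  plays no game (payoff zero).  The ``self_interaction`` variant keeps
  the cell's own type in the average (a solitary A-cell then gets ``a``).
* The division-probability formula is used in its exact ratio form
  i(1 + w*alpha) / (i(1 + w*alpha) + j(1 + w*beta)); its first-order
  expansion in w is only ever a cross-check.
* The neutral division-time profile T_n = ln((n+1)/n) makes the time to
  double a group's size equal ln 2 regardless of size, which is the
  baseline on which all life cycles grow at rate exactly 1 when w = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .games import PayoffMatrix
from .lifecycles import LifeCycle, newborn_types

__all__ = [
    "Composition",
    "ModelParams",
    "TransitionStep",
    "neutral_profile",
    "avg_payoffs",
    "division_probs",
    "division_time",
    "growth_step",
    "fragmentation_expectation",
]


@dataclass(frozen=True)
class Composition:
    """A group state: ``i`` A-cells and ``j`` B-cells (at least one cell)."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i < 0 or self.j < 0 or self.i + self.j < 1:
            raise ValueError(f"invalid composition (i={self.i}, j={self.j})")

    @property
    def size(self) -> int:
        return self.i + self.j


@dataclass(frozen=True)
class TransitionStep:
    """One merged growth transition: a size-(n+1) target and its probability."""

    target: Composition
    probability: float


def neutral_profile(n: int) -> float:
    """Size component T_n = ln((n+1)/n) of the division time.

    This profile makes the time to grow from k to 2k cells equal ln 2
    for every k (the sum telescopes), so at w = 0 every life cycle's
    population grows at rate 1.
    """
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    return math.log((n + 1) / n)


@dataclass(frozen=True)
class ModelParams:
    """Model parameters shared by all kernels.

    Parameters
    ----------
    m
        Phenotype-switching probability per daughter cell, in [0, 1].
    w
        Selection strength (>= 0, intended << 1).
    time_profile
        ``"neutral"`` for T_n = ln((n+1)/n), a sequence [T_1, T_2, ...],
        or a callable n -> T_n.
    self_interaction
        If True, payoff averages include the focal cell's own type and
        solitary cells receive their diagonal payoff.
    payoff_guard
        Admissibility bound: require w * max|payoff| < payoff_guard
        (default 0.5) so that fitness factors and division times stay
        positive.  Raise it deliberately to explore stronger selection.
    """

    m: float
    w: float = 0.0
    time_profile: str | Sequence[float] | Callable[[int], float] = "neutral"
    self_interaction: bool = False
    payoff_guard: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"switching probability m must be in [0, 1], got {self.m}")
        if self.w < 0.0:
            raise ValueError(f"selection strength w must be >= 0, got {self.w}")

    def T(self, n: int) -> float:
        """Size-dependent division-time component T_n (must be > 0)."""
        if n < 1:
            raise ValueError(f"group size must be >= 1, got {n}")
        if isinstance(self.time_profile, str):
            if self.time_profile != "neutral":
                raise ValueError(f"unknown time profile {self.time_profile!r}")
            t = neutral_profile(n)
        elif callable(self.time_profile):
            t = float(self.time_profile(n))
        else:
            try:
                t = float(self.time_profile[n - 1])
            except IndexError:
                raise ValueError(
                    f"time profile has no entry for size {n}") from None
        if t <= 0.0:
            raise ValueError(f"time profile gives non-positive T_{n} = {t}")
        return t

    def check_admissible(self, game: PayoffMatrix) -> None:
        """Reject selection too strong for the weak-selection formulas."""
        if self.w * game.max_abs_payoff >= self.payoff_guard:
            raise ValueError(
                f"w * max|payoff| = {self.w * game.max_abs_payoff:.3g} exceeds the "
                f"admissibility guard {self.payoff_guard}; the model is defined for "
                f"weak selection (reduce w or raise payoff_guard)")


def avg_payoffs(comp: Composition, game: PayoffMatrix,
                self_interaction: bool = False) -> tuple[float, float]:
    """Average payoffs (alpha, beta) of A- and B-cells in a group.

    Default (no self-interaction): alpha = ((i-1)a + jb)/(i+j-1) and
    beta = (ic + (j-1)d)/(i+j-1); a solitary cell plays no game, so
    alpha = beta = 0 at size 1.  The self-interaction variant keeps the
    focal cell's own type in the group average — alpha = (ia + jb)/(i+j),
    beta = (ic + jd)/(i+j) for groups of two or more — while solitary
    cells still play no game.  (Of the two readings of "dropping the
    self-interaction exclusion", letting solitary cells collect their
    diagonal payoff reshapes the optimality landscape drastically; the
    variant implemented here perturbs it only mildly, which is the
    behaviour the variant is meant to capture.)
    """
    i, j = comp.i, comp.j
    if i + j == 1:
        return (0.0, 0.0)
    if self_interaction:
        n = i + j
        return ((i * game.a + j * game.b) / n, (i * game.c + j * game.d) / n)
    n1 = i + j - 1
    return (((i - 1) * game.a + j * game.b) / n1,
            (i * game.c + (j - 1) * game.d) / n1)


def division_probs(comp: Composition, game: PayoffMatrix, w: float,
                   self_interaction: bool = False) -> tuple[float, float]:
    """Probability (pA, pB) that the next divider is an A- or a B-cell.

    Exact ratio form: each cell's weight is 1 + w * (its average payoff),
    so pA = i(1+w*alpha) / (i(1+w*alpha) + j(1+w*beta)).  pA + pB = 1.
    """
    alpha, beta = avg_payoffs(comp, game, self_interaction)
    fa, fb = 1.0 + w * alpha, 1.0 + w * beta
    if (comp.i > 0 and fa <= 0.0) or (comp.j > 0 and fb <= 0.0):
        raise ValueError(
            f"non-positive fitness factor at composition (i={comp.i}, j={comp.j}): "
            f"1+w*alpha={fa:.3g}, 1+w*beta={fb:.3g} — selection strength w too "
            f"large for this game")
    num_a = comp.i * fa
    denom = num_a + comp.j * fb
    pA = num_a / denom
    return (pA, 1.0 - pA)


def division_time(comp: Composition, game: PayoffMatrix,
                  params: ModelParams) -> float:
    """Waiting time t = T_{i+j} (1 - w (i*alpha + j*beta)/(i+j)) before division.

    Groups with higher average payoff divide sooner (group-level
    selection).  A non-positive time signals inadmissibly strong
    selection and is rejected.
    """
    alpha, beta = avg_payoffs(comp, game, params.self_interaction)
    n = comp.size
    t = params.T(n) * (1.0 - params.w * (comp.i * alpha + comp.j * beta) / n)
    if t <= 0.0:
        raise ValueError(
            f"non-positive division time at composition (i={comp.i}, j={comp.j}); "
            f"selection strength w={params.w} too large for this game")
    return t


def growth_step(comp: Composition, game: PayoffMatrix,
                params: ModelParams) -> list[TransitionStep]:
    """Merged one-division transition distribution from a composition.

    The mother is A with probability pA (B otherwise) and is replaced by
    two daughters, each independently switching type with probability m:
    an A-mother yields AA with (1-m)^2, AB with 2m(1-m), BB with m^2,
    mirrored for a B-mother.  Micro-outcomes landing on the same target
    composition are merged; probabilities sum to 1.
    """
    pA, pB = division_probs(comp, game, params.w, params.self_interaction)
    m = params.m
    keep2, mix, switch2 = (1.0 - m) ** 2, 2.0 * m * (1.0 - m), m * m
    i, j = comp.i, comp.j
    acc: dict[tuple[int, int], float] = {}

    def add(tgt_i: int, tgt_j: int, p: float) -> None:
        if p > 0.0:
            acc[(tgt_i, tgt_j)] = acc.get((tgt_i, tgt_j), 0.0) + p

    if pA > 0.0:
        add(i + 1, j, pA * keep2)      # A -> AA
        add(i, j + 1, pA * mix)        # A -> AB
        add(i - 1, j + 2, pA * switch2)  # A -> BB
    if pB > 0.0:
        add(i, j + 1, pB * keep2)      # B -> BB
        add(i + 1, j, pB * mix)        # B -> AB
        add(i + 2, j - 1, pB * switch2)  # B -> AA
    return [TransitionStep(Composition(ti, tj), p)
            for (ti, tj), p in sorted(acc.items(), key=lambda kv: -kv[0][0])]


def fragmentation_expectation(final: Composition, lc: LifeCycle,
                              exact: bool = False):
    """Expected newborn-type counts from fragmenting a critical-size group.

    All M cells are randomly assigned to the offspring groups, so a part
    of size s receives x A-cells with multivariate-hypergeometric
    probability C(i, x) C(M-i, s-x) / C(M, s); expectations are summed
    over parts and reported in :func:`newborn_types` order.  Combinatorics
    are done in exact rational arithmetic; with ``exact=True`` the
    Fractions themselves are returned (conservation of cells and of
    A-cells then holds identically).
    """
    M = lc.M
    if final.size != M:
        raise ValueError(
            f"final composition has size {final.size}, life cycle {lc.name} "
            f"requires size {M}")
    i = final.i
    types = newborn_types(lc)
    index = {(t.size, t.n_A): k for k, t in enumerate(types)}
    expect = [Fraction(0)] * len(types)
    denom_cache: dict[int, int] = {}
    for s in lc.parts:
        denom = denom_cache.setdefault(s, math.comb(M, s))
        for x in range(max(0, s - (M - i)), min(s, i) + 1):
            p = Fraction(math.comb(i, x) * math.comb(M - i, s - x), denom)
            expect[index[(s, x)]] += p
    if exact:
        return expect
    return np.array([float(e) for e in expect])
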