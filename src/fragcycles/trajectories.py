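"""Brute-force enumeration of developmental trajectories.

A developmental trajectory is the full record of a group's composition
from its newborn state up to the critical size M, one composition per
size.  Each trajectory tau carries the probability p(tau) of being
followed (product of merged one-division transition probabilities), a
deterministic duration T(tau) (sum of the division times of the
compositions passed through before fragmentation), and the expected
newborn-type counts N(tau) produced by the random fragmentation of its
final composition.

This module exists as the independent validation oracle for the
dynamic-programming construction in :mod:`fragcycles.growth`: the
newborn-to-newborn projection matrix

    Q_kj(lambda) = sum_tau p_k(tau) N_j(tau) exp(-lambda T(tau))

is assembled here literally, trajectory by trajectory, and must agree
entrywise with the DP result.  Enumeration is exponential in M and is
guarded accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (Composition, ModelParams, division_time,
                       fragmentation_expectation, growth_step)
from .games import PayoffMatrix
from .lifecycles import LifeCycle, NewbornType, newborn_types

__all__ = ["Trajectory", "enumerate_trajectories", "q_from_trajectories",
           "MAX_ENUMERABLE_M"]

MAX_ENUMERABLE_M = 7


@dataclass(frozen=True)
class Trajectory:
    """One composition path from a newborn state to the critical size."""

    path: tuple[Composition, ...]
    probability: float
    duration: float
    offspring_expectation: np.ndarray

    def __post_init__(self) -> None:
        sizes = [c.size for c in self.path]
        if any(b - a != 1 for a, b in zip(sizes, sizes[1:])):
            raise ValueError("trajectory sizes must increase by exactly 1")


def enumerate_trajectories(lc: LifeCycle, start: NewbornType,
                           game: PayoffMatrix,
                           params: ModelParams) -> list[Trajectory]:
    """All composition paths with nonzero probability from one newborn state.

    Probabilities over the returned list sum to 1.  Paths are aggregated
    at the composition level: division micro-outcomes that lead to the
    same next composition are merged, and the random assignment of cells
    at fragmentation is folded into the expected offspring vector of the
    final composition (exact, since the projection matrix is linear in
    the offspring counts).
    """
    if start not in newborn_types(lc):
        raise ValueError(
            f"{start!r} is not a newborn type of life cycle {lc.name}")
    params.check_admissible(game)
    out: list[Trajectory] = []
    first = Composition(start.n_A, start.size - start.n_A)

    def walk(path: list[Composition], prob: float, dur: float) -> None:
        comp = path[-1]
        if comp.size == lc.M:
            out.append(Trajectory(tuple(path), prob, dur,
                                  fragmentation_expectation(comp, lc)))
            return
        t = division_time(comp, game, params)
        for step in growth_step(comp, game, params):
            walk(path + [step.target], prob * step.probability, dur + t)

    walk([first], 1.0, 0.0)
    return out


def q_from_trajectories(lc: LifeCycle, game: PayoffMatrix,
                        params: ModelParams, lam: float) -> np.ndarray:
    """Assemble Q(lambda) by explicit summation over all trajectories.

    Entry (k, j) sums p_k(tau) N_j(tau) exp(-lambda T(tau)) over the
    trajectories starting from newborn type k.  Intended as a test
    oracle; rejects critical sizes beyond ``MAX_ENUMERABLE_M`` (use the
    dynamic-programming builder in :mod:`fragcycles.growth` instead).
    """
    if lc.M > MAX_ENUMERABLE_M:
        raise ValueError(
            f"trajectory enumeration is guarded at M <= {MAX_ENUMERABLE_M} "
            f"(got M={lc.M}); use fragcycles.growth.q_matrix")
    types = newborn_types(lc)
    S = len(types)
    Q = np.zeros((S, S))
    for k, start in enumerate(types):
        for traj in enumerate_trajectories(lc, start, game, params):
            Q[k] += (traj.probability * np.exp(-lam * traj.duration)
                     * traj.offspring_expectation)
    return Q
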