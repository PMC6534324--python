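"""Evolutionary optimality of life cycles under weak selection.

Life cycles compete on the population growth rate lambda ~ 1 + w*lambda';
under weak selection the ranking is decided by the first-order response
lambda', which depends on the game only through (psi, phi) and on the
switching probability m.  This module ranks all life cycles up to a
maximal critical size, sweeps the prisoner's-dilemma family, locates
phase boundaries by bisection, and builds (phi, m) phase maps of the
optimal life cycle for psi > 0 or psi < 0.

Two facts make dense phase maps cheap:

* lambda' is linear in the payoff entries, and the type-relabelling
  symmetry gives a and d (resp. b and c) equal weight, so
  lambda'(lc, m; psi, phi) = psi * F(lc, m) + phi * |psi| * G(lc, m)
  where F and G are the responses to the two basis games
  (a=d=1/2, b=c=0) and (a=d=0, b=c=1/2);
* F and G need one finite-difference evaluation per (lc, m) each, after
  which a whole phi grid is pure arithmetic.

``phase_map(..., method="direct")`` instead evaluates every grid cell
through its canonical representative matrix; a test asserts the two
routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .games import PayoffMatrix, matrix_from_phase_coordinates, pd_example
from .growth import lambda_prime
from .lifecycles import LifeCycle, enumerate_lifecycles

__all__ = [
    "OptimalityRecord", "PhaseMap", "optimal_lifecycles", "pd_sweep",
    "phase_map", "boundary_find", "default_phi_grid", "default_m_grid",
    "DEFAULT_TIE_TOL",
]

#: Relative tie tolerance on lambda'.  Must sit above the ~1e-7
#: finite-difference truncation noise of the lambda' estimator (so that
#: genuinely degenerate games, e.g. the donation game's tie among all
#: life cycles with multicellular offspring, are reported as ties) while
#: staying below real gaps between distinct optima.
DEFAULT_TIE_TOL = 1.0e-6


@dataclass(frozen=True)
class OptimalityRecord:
    """lambda' ranking of all life cycles at one (game, m) point."""

    game: PayoffMatrix
    m: float
    lambda_prime_by_lifecycle: dict[str, float]
    optimal_set: tuple[str, ...]
    max_lambda_prime: float

    @property
    def optimal(self) -> str:
        """The arg-max life cycle (first of the co-optimal set)."""
        return self.optimal_set[0]

    @property
    def is_tie(self) -> bool:
        return len(self.optimal_set) > 1


@dataclass(frozen=True)
class PhaseMap:
    """Optimal life cycle over a (phi, m) grid at fixed sign of psi.

    ``table`` has one row per grid cell with columns phi, m, optimal,
    n_coopt, lambda_prime_max, co_optimal.  The census counts the
    distinct strict optima — cells where the optimal set is a singleton;
    tie cells (measure-zero boundaries such as the phi = 1 line) are
    reported but excluded from the census.
    """

    psi_sign: int
    phi_grid: np.ndarray
    m_grid: np.ndarray
    max_M: int
    tie_tol: float
    self_interaction: bool
    table: pd.DataFrame

    @property
    def census(self) -> tuple[str, ...]:
        strict = self.table.loc[self.table["n_coopt"] == 1, "optimal"]
        names = sorted(set(strict), key=lambda s: (len(s), s))
        return tuple(names)


def _tie_set(names: Sequence[str], values: np.ndarray,
             tie_tol: float) -> tuple[tuple[str, ...], float]:
    vmax = float(values.max())
    tol = tie_tol * max(1.0, abs(vmax))
    members = tuple(n for n, v in zip(names, values) if vmax - v <= tol)
    return members, vmax


def optimal_lifecycles(game: PayoffMatrix, m: float, max_M: int = 7,
                       tie_tol: float = DEFAULT_TIE_TOL,
                       self_interaction: bool = False) -> OptimalityRecord:
    """Rank every life cycle with critical size up to max_M by lambda'.

    Co-optimal life cycles (within ``tie_tol`` relative to the maximum)
    are all reported; ties are never silently broken.
    """
    lcs = enumerate_lifecycles(max_M)
    names = [lc.name for lc in lcs]
    values = np.array([
        lambda_prime(lc, game, m, self_interaction=self_interaction).lambda_prime
        for lc in lcs])
    optimal_set, vmax = _tie_set(names, values, tie_tol)
    return OptimalityRecord(game=game, m=m,
                            lambda_prime_by_lifecycle=dict(zip(names, values)),
                            optimal_set=optimal_set, max_lambda_prime=vmax)


def pd_sweep(c_values: Iterable[float], m: float = 0.5, max_M: int = 7,
             tie_tol: float = DEFAULT_TIE_TOL) -> pd.DataFrame:
    """Optimal life cycles along the prisoner's-dilemma family (1, -3, c, 0).

    Returns one row per c with the optimal (or co-optimal) life cycles
    and the top lambda'.  The family has psi = 1 and phi = c - 3, so the
    sweep traverses the phi axis at fixed psi > 0.
    """
    rows = []
    for c in c_values:
        rec = optimal_lifecycles(pd_example(c), m, max_M, tie_tol)
        rows.append({
            "c": c, "phi": c - 3.0, "m": m,
            "optimal": rec.optimal,
            "n_coopt": len(rec.optimal_set),
            "co_optimal": ",".join(rec.optimal_set),
            "lambda_prime_max": rec.max_lambda_prime,
        })
    return pd.DataFrame(rows)


def boundary_find(lc1: LifeCycle, lc2: LifeCycle,
                  family: Callable[[float], PayoffMatrix],
                  bracket: tuple[float, float], m: float,
                  xtol: float = 1.0e-4,
                  self_interaction: bool = False) -> float:
    """Locate the parameter where lambda'(lc1) and lambda'(lc2) cross.

    ``family`` maps a scalar parameter to a game; the difference must
    change sign across ``bracket``.  Root by Brent's method to ``xtol``.
    """
    if lc1 == lc2:
        raise ValueError("boundary between a life cycle and itself is undefined")

    def diff(p: float) -> float:
        g = family(p)
        return (lambda_prime(lc1, g, m, self_interaction).lambda_prime
                - lambda_prime(lc2, g, m, self_interaction).lambda_prime)

    lo, hi = bracket
    flo, fhi = diff(lo), diff(hi)
    if np.sign(flo) == np.sign(fhi):
        raise ValueError(
            f"lambda' difference does not change sign on {bracket}: "
            f"f({lo})={flo:.3g}, f({hi})={fhi:.3g}")
    return float(brentq(diff, lo, hi, xtol=xtol))


def default_phi_grid() -> np.ndarray:
    """phi in [-8, 3] step 0.05, refined to 0.01 on [0.8, 1.2].

    The strongly negative reach matters: the rare transitional optima
    (2+1, 2+1+1) occupy small windows at phi well below -1 and small m,
    between the multiple-fission and 2+2 regions.  The fine window around
    phi = 1 resolves the boundary where all multicellular-offspring life
    cycles become degenerate.
    """
    base = np.arange(-8.0, 3.0 + 1e-9, 0.05)
    fine = np.arange(0.8, 1.2 + 1e-9, 0.01)
    return np.unique(np.round(np.concatenate([base, fine]), 9))


def default_m_grid() -> np.ndarray:
    """Switching probabilities: 25 log points on [1e-3, 0.1], then steps.

    Linear steps of 0.02 up to 0.98, refined to 0.01 on [0.5, 0.99]: the
    small-m decade hosts the multiple-fission optima (1+...+1 at sizes 3,
    4, 5) and the rare 2+1+1, the large-m refinement the rare 2+1.
    """
    log_part = np.logspace(-3.0, -1.0, 25)
    lin_part = np.arange(0.1, 0.99, 0.02)
    fine = np.arange(0.5, 0.99 + 1e-9, 0.01)
    return np.unique(np.round(np.concatenate([log_part, lin_part, fine]), 9))


def _basis_responses(lcs: Sequence[LifeCycle], m_grid: np.ndarray,
                     self_interaction: bool) -> tuple[np.ndarray, np.ndarray]:
    """F(lc, m) and G(lc, m): lambda' of the two payoff basis games."""
    basis_psi = PayoffMatrix(0.5, 0.0, 0.0, 0.5)   # psi = 1, b + c = 0
    basis_bc = PayoffMatrix(0.0, 0.5, 0.5, 0.0)    # psi = 0, b + c = 1
    F = np.empty((len(lcs), len(m_grid)))
    G = np.empty_like(F)
    for li, lc in enumerate(lcs):
        for mi, m in enumerate(m_grid):
            F[li, mi] = lambda_prime(lc, basis_psi, float(m),
                                     self_interaction=self_interaction).lambda_prime
            G[li, mi] = lambda_prime(lc, basis_bc, float(m),
                                     self_interaction=self_interaction).lambda_prime
    return F, G


def phase_map(psi_sign: int, phi_grid: np.ndarray | None = None,
              m_grid: np.ndarray | None = None, max_M: int = 7,
              tie_tol: float = DEFAULT_TIE_TOL,
              self_interaction: bool = False,
              method: str = "linear") -> PhaseMap:
    """Optimal life cycle over a (phi, m) grid at psi = +1 or -1.

    ``method="linear"`` exploits the linearity of lambda' in the payoff
    entries: per (life cycle, m) only the two basis-game responses are
    solved for, and every phi cell follows by arithmetic.
    ``method="direct"`` evaluates lambda' of the canonical representative
    matrix at every cell (slow; used for cross-validation).
    """
    if psi_sign not in (1, -1):
        raise ValueError(f"psi_sign must be +1 or -1, got {psi_sign!r}")
    if method not in ("linear", "direct"):
        raise ValueError(f"unknown method {method!r}")
    phi_grid = default_phi_grid() if phi_grid is None else np.asarray(phi_grid, float)
    m_grid = default_m_grid() if m_grid is None else np.asarray(m_grid, float)
    lcs = enumerate_lifecycles(max_M)
    names = [lc.name for lc in lcs]

    rows = []
    if method == "linear":
        F, G = _basis_responses(lcs, m_grid, self_interaction)
        for mi, m in enumerate(m_grid):
            base = psi_sign * F[:, mi]
            for phi in phi_grid:
                values = base + phi * G[:, mi]
                members, vmax = _tie_set(names, values, tie_tol)
                rows.append((float(phi), float(m), members[0], len(members),
                             vmax, ",".join(members)))
    else:
        for m in m_grid:
            for phi in phi_grid:
                g = matrix_from_phase_coordinates(psi_sign, float(phi))
                rec = optimal_lifecycles(g, float(m), max_M, tie_tol,
                                         self_interaction)
                rows.append((float(phi), float(m), rec.optimal,
                             len(rec.optimal_set), rec.max_lambda_prime,
                             ",".join(rec.optimal_set)))
    table = pd.DataFrame(rows, columns=["phi", "m", "optimal", "n_coopt",
                                        "lambda_prime_max", "co_optimal"])
    return PhaseMap(psi_sign=psi_sign, phi_grid=phi_grid, m_grid=m_grid,
                    max_M=max_M, tie_tol=tie_tol,
                    self_interaction=self_interaction, table=table)
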