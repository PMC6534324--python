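"""Population growth rate of a life cycle.

In the long run a population of independently growing, fragmenting
groups grows exponentially at a rate lambda determined by the
characteristic condition det(Q(lambda) - I) = 0, where Q(lambda) is the
newborn-to-newborn projection matrix: entry (k, j) is the discounted
expected number of type-j newborns produced per type-k newborn,

    Q_kj(lambda) = sum_tau p_k(tau) N_j(tau) exp(-lambda T(tau)).

Because every entry of Q is a sum of positive terms exp(-lambda T) with
T > 0, the spectral radius rho(Q(lambda)) is strictly decreasing in
lambda, so the growth rate is the unique root of rho(Q(lambda)) = 1.
Working with rho rather than the determinant keeps the root objective
monotone and sign-stable.

The sum over trajectories factorises over the composition path, so
Q(lambda) is built by a forward dynamic program over compositions —
cost polynomial in M instead of exponential — and is checked against the
literal trajectory sum in :mod:`fragcycles.trajectories`.

Under the neutral division-time profile every life cycle has lambda = 1
at w = 0; the first-order response lambda' = d(lambda)/dw at w = 0 is
the quantity life cycles compete on under weak selection.  It is
estimated by Richardson-extrapolated finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .dynamics import (Composition, ModelParams, division_time,
                       fragmentation_expectation, growth_step)
from .games import PayoffMatrix
from .lifecycles import LifeCycle, newborn_types

__all__ = ["GrowthResult", "WeakSelectionResult", "QBuilder", "q_matrix",
           "growth_rate", "lambda_prime"]

#: Richardson finite-difference steps for lambda'; the larger step is
#: exactly twice the smaller, which cancels the second-order term.
W_FD_LARGE = 1.0e-3
W_FD_SMALL = 5.0e-4


@dataclass(frozen=True)
class GrowthResult:
    """Growth rate lambda with solver diagnostics."""

    lam: float
    bracket: tuple[float, float]
    xtol: float
    residual: float  # |rho(Q(lambda)) - 1|


@dataclass(frozen=True)
class WeakSelectionResult:
    """First-order growth response lambda' = d(lambda)/dw at w = 0."""

    lambda_prime: float
    w_used: tuple[float, float]
    method: str


class QBuilder:
    """Precomputed dynamic program for Q(lambda) at fixed (lc, game, params).

    All lambda-independent pieces — per-size division times, one-division
    transition matrices, and the fragmentation contraction — are built
    once; evaluating Q (or its spectral radius) at a given lambda is then
    a handful of small matrix products, which makes root solving in
    lambda cheap.
    """

    def __init__(self, lc: LifeCycle, game: PayoffMatrix,
                 params: ModelParams) -> None:
        params.check_admissible(game)
        if params.m in (0.0, 1.0):
            warnings.warn(
                f"m={params.m}: phenotype switching does not mix the types, "
                "Q(lambda) may be reducible; the spectral radius is still "
                "well defined", stacklevel=2)
        self.lc = lc
        self.game = game
        self.params = params
        self.types = newborn_types(lc)
        self.S = len(self.types)
        M = lc.M
        self._start_sizes = sorted(set(lc.parts))
        # composition index at size n is the A-cell count i = 0..n
        self._t: dict[int, np.ndarray] = {}
        self._B: dict[int, np.ndarray] = {}
        for n in range(self._start_sizes[0], M):
            t_vec = np.empty(n + 1)
            B = np.zeros((n + 1, n + 2))
            for i in range(n + 1):
                comp = Composition(i, n - i)
                t_vec[i] = division_time(comp, game, params)
                for step in growth_step(comp, game, params):
                    B[i, step.target.i] += step.probability
            self._t[n] = t_vec
            self._B[n] = B
        self._frag = np.zeros((M + 1, self.S))
        for i in range(M + 1):
            self._frag[i] = fragmentation_expectation(Composition(i, M - i), lc)
        # row index in Q for newborn type (s, x)
        self._row = {(t.size, t.n_A): k for k, t in enumerate(self.types)}

    def q(self, lam: float) -> np.ndarray:
        """Evaluate Q(lambda)."""
        M = self.lc.M
        Q = np.empty((self.S, self.S))
        for s in self._start_sizes:
            W = np.eye(s + 1)  # row x: started as (x, s - x)
            for n in range(s, M):
                W = (W * np.exp(-lam * self._t[n])) @ self._B[n]
            block = W @ self._frag
            for x in range(s + 1):
                Q[self._row[(s, x)]] = block[x]
        return Q

    def spectral_radius(self, lam: float) -> float:
        return float(np.abs(np.linalg.eigvals(self.q(lam))).max())


def q_matrix(lc: LifeCycle, game: PayoffMatrix, params: ModelParams,
             lam: float) -> np.ndarray:
    """Q(lambda) via the dynamic program (one-shot convenience wrapper)."""
    return QBuilder(lc, game, params).q(lam)


def _bracket_root(f, lo: float, hi: float,
                  lo_min: float = 1.0e-3, hi_max: float = 16.0):
    """Expand (lo, hi) geometrically until f(lo) > 0 > f(hi)."""
    flo, fhi = f(lo), f(hi)
    while flo <= 0.0:
        if lo <= lo_min:
            raise RuntimeError(
                f"failed to bracket the growth rate: rho(Q) <= 1 down to "
                f"lambda={lo:.3g} (f={flo:.3g})")
        lo = max(lo / 2.0, lo_min)
        flo = f(lo)
    while fhi >= 0.0:
        if hi >= hi_max:
            raise RuntimeError(
                f"failed to bracket the growth rate: rho(Q) >= 1 up to "
                f"lambda={hi:.3g} (f={fhi:.3g})")
        hi = min(hi * 2.0, hi_max)
        fhi = f(hi)
    return lo, hi


def growth_rate(lc: LifeCycle, game: PayoffMatrix, params: ModelParams,
                bracket: tuple[float, float] = (0.5, 1.5),
                xtol: float = 1.0e-12) -> GrowthResult:
    """Solve rho(Q(lambda)) = 1 for the population growth rate.

    The spectral radius is strictly decreasing in lambda, so the root is
    unique; the initial bracket (default (0.5, 1.5), centred on the
    neutral rate 1) is expanded geometrically to [1e-3, 16] before the
    solve is abandoned.
    """
    builder = QBuilder(lc, game, params)
    f = lambda lam: builder.spectral_radius(lam) - 1.0
    lo, hi = _bracket_root(f, *bracket)
    lam = brentq(f, lo, hi, xtol=xtol)
    return GrowthResult(lam=float(lam), bracket=(lo, hi), xtol=xtol,
                        residual=abs(f(lam)))


def lambda_prime(lc: LifeCycle, game: PayoffMatrix, m: float,
                 self_interaction: bool = False,
                 w_steps: tuple[float, float] = (W_FD_LARGE, W_FD_SMALL),
                 xtol: float = 1.0e-13) -> WeakSelectionResult:
    """Weak-selection growth derivative lambda' = d(lambda)/dw at w = 0.

    Uses the neutral division-time profile, for which lambda(0) = 1
    exactly, and Richardson-extrapolated one-sided differences: with
    steps w1 = 2*w2,

        lambda' = 2 (lambda(w2) - 1)/w2 - (lambda(w1) - 1)/w1,

    which cancels the O(w) term and leaves O(w2^2) ~ 1e-7 truncation on
    top of ~1e-9 solver noise.  Deterministic for given inputs.
    """
    w1, w2 = w_steps
    if not (w1 > w2 > 0.0):
        raise ValueError(f"w_steps must satisfy w1 > w2 > 0, got {w_steps}")
    base = ModelParams(m=m, time_profile="neutral",
                       self_interaction=self_interaction)
    slopes = []
    for w in (w1, w2):
        res = growth_rate(lc, game, replace(base, w=w),
                          bracket=(0.8, 1.2), xtol=xtol)
        slopes.append((res.lam - 1.0) / w)
    lp = 2.0 * slopes[1] - slopes[0]
    return WeakSelectionResult(lambda_prime=lp, w_used=(w1, w2),
                               method="richardson-2pt-forward-fd")
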