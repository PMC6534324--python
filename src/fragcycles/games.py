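"""Two-player games between cell phenotypes.

Interactions between the two cell types A and B are captured by a 2x2
payoff matrix (a, b, c, d): an A-cell receives ``a`` against A and ``b``
against B, while a B-cell receives ``c`` against A and ``d`` against B.

Under weak selection the growth-rate consequences of a game collapse onto
two summary coordinates,

* ``psi = a + d`` — whether forming a homogeneous group pays off relative
  to a solitary cell (which plays no game and collects zero payoff), and
* ``phi = (b + c) / |a + d|`` — the performance of heterogeneous groups
  relative to homogeneous ones (defined only for ``psi != 0``),

so the whole space of 2x2 games is summarised by (psi, phi) together with
the phenotype-switching probability m.  This module provides the matrix
container, the (psi, phi) summary, the standard replicator-dynamics
classification (dominance / bistability / coexistence) and constructors
for the named games used throughout: the donation game, the snowdrift
game, the stag hunt, and a one-parameter prisoner's-dilemma family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "PayoffMatrix",
    "GameSummary",
    "summarize",
    "donation",
    "snowdrift",
    "stag_hunt",
    "pd_example",
    "named_game",
    "matrix_from_phase_coordinates",
    "NAMED_GAMES",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """A 2x2 game between cell types A and B.

    Parameters
    ----------
    a, b, c, d
        Payoffs: A receives `a` from A and `b` from B; B receives `c`
        from A and `d` from B.  All entries must be finite.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"payoff entry {name}={v!r} is not finite")

    def swapped(self) -> "PayoffMatrix":
        """The game seen after relabelling the cell types A <-> B.

        The relabelling exchanges a <-> d and b <-> c; population-level
        quantities are invariant under the combined swap of types and
        payoffs.
        """
        return PayoffMatrix(self.d, self.c, self.b, self.a)

    @property
    def max_abs_payoff(self) -> float:
        return max(abs(self.a), abs(self.b), abs(self.c), abs(self.d))


@dataclass(frozen=True)
class GameSummary:
    """(psi, phi) coordinates and replicator-dynamics class of a game.

    ``phi`` is ``None`` when ``psi == 0`` (``phi_defined`` is False); the
    raw sum b + c is always carried in ``raw_bc``.  ``dynamics_class`` is
    one of ``"dominance"``, ``"bistability"``, ``"coexistence"`` or
    ``"neutral"`` (the latter whenever one of the defining comparisons is
    an exact tie).
    """

    psi: float
    phi: float | None
    phi_defined: bool
    raw_bc: float
    dynamics_class: str


def summarize(game: PayoffMatrix) -> GameSummary:
    """Compute the (psi, phi) summary and dynamics class of a game.

    Bistability requires a > c and b < d (both pure states stable under
    replicator dynamics); coexistence requires a < c and b > d; strict
    inequalities pointing the same way give dominance; any exact tie is
    reported as neutral.
    """
    psi = game.a + game.d
    raw_bc = game.b + game.c
    phi_defined = psi != 0.0
    phi = raw_bc / abs(psi) if phi_defined else None

    if game.a > game.c and game.b < game.d:
        cls = "bistability"
    elif game.a < game.c and game.b > game.d:
        cls = "coexistence"
    elif (game.a > game.c and game.b > game.d) or (game.a < game.c and game.b < game.d):
        cls = "dominance"
    else:
        cls = "neutral"
    return GameSummary(psi=psi, phi=phi, phi_defined=phi_defined,
                       raw_bc=raw_bc, dynamics_class=cls)


def donation(benefit: float, cost: float) -> PayoffMatrix:
    """Donation game: cooperators pay ``cost`` to hand the partner ``benefit``.

    Requires benefit > cost > 0.  The matrix is
    ((benefit - cost, -cost), (benefit, 0)); its summary always has
    phi = 1 and psi = benefit - cost > 0.
    """
    if not (benefit > cost > 0):
        raise ValueError(
            f"donation game requires benefit > cost > 0, got benefit={benefit}, cost={cost}")
    return PayoffMatrix(benefit - cost, -cost, benefit, 0.0)


def snowdrift(benefit: float, cost: float) -> PayoffMatrix:
    """Snowdrift game: a shared cost buys each player ``benefit``.

    Requires benefit > cost > 0.  The matrix is
    ((benefit - cost/2, benefit - cost), (benefit, 0)); its summary always
    has phi = 2 and psi = benefit - cost/2 > 0.
    """
    if not (benefit > cost > 0):
        raise ValueError(
            f"snowdrift game requires benefit > cost > 0, got benefit={benefit}, cost={cost}")
    return PayoffMatrix(benefit - cost / 2.0, benefit - cost, benefit, 0.0)


def stag_hunt(stag: float, hare: float) -> PayoffMatrix:
    """Stag hunt: hunting the stag pays ``stag`` but needs both players.

    Requires stag > hare > 0.  The matrix is ((stag, 0), (hare, hare));
    its summary has psi = stag + hare > 0 and 0 < phi < 1/2, and the
    dynamics class is bistability.
    """
    if not (stag > hare > 0):
        raise ValueError(
            f"stag hunt requires stag > hare > 0, got stag={stag}, hare={hare}")
    return PayoffMatrix(stag, 0.0, hare, hare)


def pd_example(c: float) -> PayoffMatrix:
    """One-parameter family (1, -3, c, 0); a prisoner's dilemma for 1 < c < 5.

    The summary is psi = 1, phi = c - 3, so sweeping c traverses the phi
    axis at fixed psi.
    """
    return PayoffMatrix(1.0, -3.0, c, 0.0)


NAMED_GAMES: Mapping[str, object] = {
    "donation": donation,
    "snowdrift": snowdrift,
    "stag_hunt": stag_hunt,
    "pd_example": pd_example,
}


def named_game(name: str, **params: float) -> PayoffMatrix:
    """Construct a named game; see :data:`NAMED_GAMES` for the catalogue."""
    try:
        ctor = NAMED_GAMES[name]
    except KeyError:
        raise ValueError(
            f"unknown game {name!r}; known games: {sorted(NAMED_GAMES)}") from None
    return ctor(**params)


def matrix_from_phase_coordinates(psi_sign: int, phi: float) -> PayoffMatrix:
    """Canonical game representative with psi = psi_sign and the given phi.

    Uses the symmetric convention a = d = psi_sign/2, b = c = phi/2, so
    the A<->B relabelling is an exact identity of the matrix itself.  Any
    representative would do, since the weak-selection growth derivative
    depends on the game only through (psi, phi).
    """
    if psi_sign not in (1, -1):
        raise ValueError(f"psi_sign must be +1 or -1, got {psi_sign!r}")
    if not math.isfinite(phi):
        raise ValueError(f"phi must be finite, got {phi!r}")
    half = psi_sign / 2.0
    return PayoffMatrix(half, phi / 2.0, phi / 2.0, half)
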