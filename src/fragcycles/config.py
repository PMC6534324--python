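"""Run configuration: parsing, validation, round-tripping.

A run is described by a flat mapping (YAML or JSON file, or CLI flags):
a game — either four raw payoffs or a named game plus its parameters —
the switching probability m, selection strength w, maximal critical size,
division-time profile, optional life cycle, grids, seed and output path.
Configurations round-trip losslessly through ``to_dict``/``from_dict``
and hash stably, so every emitted result can name the exact
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dynamics import ModelParams
from .games import NAMED_GAMES, PayoffMatrix, named_game
from .lifecycles import LifeCycle

__all__ = ["RunConfig", "game_from_spec", "load_config"]


def game_from_spec(spec: Mapping[str, Any]) -> PayoffMatrix:
    """Build a game from a mapping.

    Either ``{"payoffs": [a, b, c, d]}`` or
    ``{"name": "<game>", "params": {...}}`` (e.g.
    ``{"name": "donation", "params": {"benefit": 2, "cost": 1}}``).
    """
    if "payoffs" in spec:
        payoffs = spec["payoffs"]
        if len(payoffs) != 4:
            raise ValueError(
                f"field 'payoffs' must have exactly 4 entries, got {payoffs!r}")
        return PayoffMatrix(*(float(v) for v in payoffs))
    if "name" in spec:
        name = spec["name"]
        if name not in NAMED_GAMES:
            raise ValueError(
                f"field 'name': unknown game {name!r}; known: {sorted(NAMED_GAMES)}")
        params = {k: float(v) for k, v in dict(spec.get("params", {})).items()}
        return named_game(name, **params)
    raise ValueError("game spec needs either 'payoffs' or 'name'")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one CLI run."""

    game: dict[str, Any]
    m: float
    w: float = 1.0e-3
    max_M: int = 7
    lifecycle: str | None = None
    time_profile: str | list[float] = "neutral"
    self_interaction: bool = False
    seed: int = 0
    out: str | None = None
    fmt: str = "csv"

    def __post_init__(self) -> None:
        game_from_spec(self.game)  # validates eagerly
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"field 'm' must be in [0, 1], got {self.m}")
        if self.w < 0.0:
            raise ValueError(f"field 'w' must be >= 0, got {self.w}")
        if self.max_M < 2:
            raise ValueError(f"field 'max_M' must be >= 2, got {self.max_M}")
        if self.lifecycle is not None:
            LifeCycle.from_name(self.lifecycle)
        if self.fmt not in ("csv", "json"):
            raise ValueError(f"field 'fmt' must be csv or json, got {self.fmt!r}")

    @property
    def payoff_matrix(self) -> PayoffMatrix:
        return game_from_spec(self.game)

    @property
    def life_cycle(self) -> LifeCycle | None:
        return None if self.lifecycle is None else LifeCycle.from_name(self.lifecycle)

    def model_params(self, w: float | None = None) -> ModelParams:
        profile = (self.time_profile if isinstance(self.time_profile, str)
                   else list(self.time_profile))
        return ModelParams(m=self.m, w=self.w if w is None else w,
                           time_profile=profile,
                           self_interaction=self.self_interaction)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(**dict(d))

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)
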