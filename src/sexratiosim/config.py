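"""Simulation configuration: all model, sampling and replication parameters.

A single frozen dataclass holds every knob of the virtual-ecologist
simulation. Female movement probability is never stored: it is derived as
``1 - male_move_prob``, which is the one-parameter encoding of the
movement asymmetry between the sexes.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "load_config", "save_config", "DEFAULTS"]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated survey.

    Parameters
    ----------
    grid_resolution
        N; the geographical domain is an N x N cell grid.
    density_multiplier
        a; total population size is ``n = a * N**2`` (half males, half
        females).
    male_move_prob
        m; per-time-step probability that a male relocates. Females
        relocate with probability ``1 - m``.
    male_detectability, female_detectability
        Per-encounter probability that an active searcher records an
        individual of that sex. Has no effect on passive (trap) capture.
    passive_effort
        Fraction of the grid resolution converted into the number of fixed
        trap transects (``round(passive_effort * N)``, minimum 1).
    burn_in_steps
        Movement-only steps before sampling starts, letting the spatial
        distribution reflect movement behaviour.
    sampling_days
        Time steps with sampling (one active transect per day).
    replicates
        Independent runs per parameter combination.
    alpha
        Significance level of the chi-square sex-ratio test.
    seed
        Base RNG seed; replicate ``i`` uses ``seed + i``.
    """

    grid_resolution: int = 20
    density_multiplier: int = 4
    male_move_prob: float = 0.5
    male_detectability: float = 0.5
    female_detectability: float = 0.5
    passive_effort: float = 0.10
    burn_in_steps: int = 100
    sampling_days: int = 100
    replicates: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.grid_resolution, int) and self.grid_resolution >= 1):
            raise ValueError("grid_resolution must be a positive integer")
        if not (isinstance(self.density_multiplier, int) and self.density_multiplier >= 1):
            raise ValueError("density_multiplier must be a positive integer")
        for name in ("male_move_prob", "male_detectability", "female_detectability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if not 0.0 < self.passive_effort <= 1.0:
            raise ValueError(f"passive_effort={self.passive_effort!r} must lie in (0, 1]")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be non-negative")
        if self.sampling_days < 0:
            raise ValueError("sampling_days must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_individuals % 2 != 0:
            raise ValueError(
                f"population size a*N**2 = {self.n_individuals} is odd; "
                "an equal sex split is impossible"
            )

    @property
    def female_move_prob(self) -> float:
        """Derived female movement probability, exactly ``1 - m``."""
        return 1.0 - self.male_move_prob

    @property
    def n_individuals(self) -> int:
        """Total population size ``n = a * N**2``."""
        return self.density_multiplier * self.grid_resolution**2

    @property
    def n_cells(self) -> int:
        return self.grid_resolution**2

    @property
    def n_passive_transects(self) -> int:
        """Number of fixed trap transects: round(effort * N), minimum 1.

        Rounding is half-away-from-zero, so an effort of 0.10 on an 8-cell
        grid (0.8 transects) still installs one transect.
        """
        return max(1, math.floor(self.passive_effort * self.grid_resolution + 0.5))

    def replace(self, **changes: Any) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


DEFAULTS = SimulationConfig()

_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a flat YAML mapping.

    Unknown keys are rejected loudly; omitted keys take their documented
    defaults; invariant violations raise ``ValueError`` naming the field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as flat YAML; round-trips through :func:`load_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
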