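"""Population state and the per-time-step movement update.

The population is a fixed set of individually identified animals (the
mark-recapture premise: captures recognise individuals, they never remove
them). State is held in flat numpy arrays; the external coordinate
convention is 1-based ``(row, column)``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, NamedTuple

import numpy as np

from .config import SimulationConfig
from .kernel import DistanceKernel

__all__ = ["Individual", "Population", "init_population", "step_movement", "run_burn_in"]


class Individual(NamedTuple):
    """One animal: stable id, sex, and current 1-based (row, col) cell."""

    id: int
    sex: str  # "male" | "female"
    cell: tuple[int, int]


@dataclasses.dataclass
class Population:
    """Positions and sexes of all individuals, with persistent identities.

    Attributes
    ----------
    N : grid resolution.
    ids : ndarray of int, stable across all time steps of a replicate.
    is_male : boolean ndarray, one entry per individual.
    cell : ndarray of flat 0-based cell indices in ``[0, N**2)``.
    """

    N: int
    ids: np.ndarray
    is_male: np.ndarray
    cell: np.ndarray

    @property
    def size(self) -> int:
        return self.ids.shape[0]

    @property
    def counts_by_sex(self) -> dict[str, int]:
        males = int(self.is_male.sum())
        return {"male": males, "female": self.size - males}

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Current positions as 1-based (row, column) arrays."""
        r, c = np.divmod(self.cell, self.N)
        return r + 1, c + 1

    def __iter__(self) -> Iterator[Individual]:
        rows, cols = self.coords()
        for i in range(self.size):
            yield Individual(
                int(self.ids[i]),
                "male" if self.is_male[i] else "female",
                (int(rows[i]), int(cols[i])),
            )


def init_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Place ``a * N**2`` individuals uniformly at random on the grid.

    Exactly half are male and half female; ids run 1..n with males first
    (ids are labels, not positions — assignment order carries no spatial
    information because every cell draw is independent and uniform).
    """
    n = config.n_individuals
    half = n // 2
    is_male = np.zeros(n, dtype=bool)
    is_male[:half] = True
    cell = rng.integers(0, config.n_cells, size=n)
    return Population(
        N=config.grid_resolution,
        ids=np.arange(1, n + 1),
        is_male=is_male,
        cell=cell,
    )


def step_movement(
    pop: Population,
    kernel: DistanceKernel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the population one time step; return the moved mask.

    Each individual independently relocates with probability ``m`` (males)
    or ``1 - m`` (females); movers draw a destination from the
    inverse-distance kernel row of their current cell. Updates are
    simultaneous (individuals do not interact). The boolean mask of
    individuals that moved this step is returned because passive traps
    capture on arrival only.
    """
    if kernel.N != pop.N:
        raise ValueError("kernel and population were built for different grid resolutions")
    p_move = np.where(pop.is_male, config.male_move_prob, config.female_move_prob)
    moved = rng.random(pop.size) < p_move
    if moved.any():
        pop.cell[moved] = kernel.draw_destinations(pop.cell[moved], rng)
    return moved


def run_burn_in(
    pop: Population,
    kernel: DistanceKernel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Population:
    """Apply ``burn_in_steps`` movement steps with no sampling.

    Lets the spatial distribution reflect each sex's movement behaviour
    instead of the uniform initial placement.
    """
    for _ in range(config.burn_in_steps):
        step_movement(pop, kernel, config, rng)
    return pop
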