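"""Capture geometry and logic for the passive and active sampling methods.

Passive method: fixed trap transects installed once per replicate. Each
transect occupies half a grid row, with stations on alternating cells
(trap, gap, trap, ...); any individual whose movement step ends on a
station cell is recorded. Detectability plays no role.

Active method: one transect per sampling day, re-drawn uniformly at
random; the observer visits every cell of the transect and records each
individual present with a sex-specific detection probability.

Both methods observe the same population trajectory and never remove
individuals; capture logs use set semantics so each individual counts at
most once per method, as in a mark-recapture survey.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import SimulationConfig
from .population import Population

__all__ = [
    "Transect",
    "TrapLayout",
    "CaptureLog",
    "build_trap_layout",
    "choose_active_transect",
    "apply_passive_capture",
    "apply_active_capture",
    "run_sampling_phase",
]


@dataclasses.dataclass(frozen=True)
class Transect:
    """A contiguous half-row segment of cells, 1-based coordinates.

    Length is ``floor(N / 2)`` and ``start_col`` ranges over
    ``1..floor(N / 2)``, so the transect always fits in the domain.
    """

    row: int
    start_col: int
    length: int

    @property
    def cells(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.row, self.start_col + k) for k in range(self.length))

    def cell_indices(self, N: int) -> np.ndarray:
        """Flat 0-based indices of the transect's cells."""
        cols = np.arange(self.start_col - 1, self.start_col - 1 + self.length)
        return (self.row - 1) * N + cols


@dataclasses.dataclass(frozen=True)
class TrapLayout:
    """The fixed passive stations for a whole replicate.

    ``trap_cell_mask`` is a boolean array over the N**2 flat cells for
    O(1) membership tests during capture.
    """

    N: int
    transects: tuple[Transect, ...]
    trap_cell_mask: np.ndarray

    @property
    def trap_cells(self) -> frozenset[tuple[int, int]]:
        """1-based (row, col) coordinates of every station."""
        idx = np.flatnonzero(self.trap_cell_mask)
        r, c = np.divmod(idx, self.N)
        return frozenset(zip((r + 1).tolist(), (c + 1).tolist()))


@dataclasses.dataclass
class CaptureLog:
    """Unique individuals recorded by each method (boolean masks over ids).

    An individual may appear in both methods' sets: the methods tally
    independently. Sets only grow; repeat captures are absorbed.
    """

    passive_mask: np.ndarray
    active_mask: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "CaptureLog":
        return cls(np.zeros(n, dtype=bool), np.zeros(n, dtype=bool))

    def passive_ids(self, pop: Population) -> frozenset[int]:
        return frozenset(pop.ids[self.passive_mask].tolist())

    def active_ids(self, pop: Population) -> frozenset[int]:
        return frozenset(pop.ids[self.active_mask].tolist())


def _transect_length(N: int) -> int:
    return N // 2


def build_trap_layout(config: SimulationConfig, rng: np.random.Generator) -> TrapLayout:
    """Install ``round(passive_effort * N)`` trap transects on distinct rows.

    Rows are drawn uniformly without replacement; each transect's start
    column is uniform in ``1..floor(N/2)``; stations occupy alternating
    cells beginning with the transect's first cell, giving
    ``ceil(length / 2)`` stations per transect. The layout is fixed for
    the whole replicate.
    """
    N = config.grid_resolution
    if N < 2:
        raise ValueError("passive sampling needs a grid of at least 2 x 2 cells")
    n_tr = config.n_passive_transects
    if n_tr > N:
        raise ValueError(
            f"passive_effort={config.passive_effort} requests {n_tr} transects "
            f"but the grid has only {N} rows"
        )
    length = _transect_length(N)
    rows = rng.choice(N, size=n_tr, replace=False) + 1
    start_cols = rng.integers(1, length + 1, size=n_tr)
    transects = tuple(
        Transect(int(r), int(s), length) for r, s in zip(rows, start_cols)
    )
    mask = np.zeros(N * N, dtype=bool)
    for tr in transects:
        mask[tr.cell_indices(N)[::2]] = True  # trap, gap, trap, ...
    return TrapLayout(N=N, transects=transects, trap_cell_mask=mask)


def choose_active_transect(config: SimulationConfig, rng: np.random.Generator) -> Transect:
    """Draw one day's active-search transect, uniform over rows and starts.

    Unlike the trap layout, a fresh transect is drawn every sampling day
    and ALL of its cells are searched (no alternating gaps).
    """
    N = config.grid_resolution
    if N < 2:
        raise ValueError("active search needs a grid of at least 2 x 2 cells")
    length = _transect_length(N)
    row = int(rng.integers(1, N + 1))
    start_col = int(rng.integers(1, length + 1))
    return Transect(row, start_col, length)


def apply_passive_capture(
    pop: Population,
    moved: np.ndarray,
    layout: TrapLayout,
    log: CaptureLog,
) -> CaptureLog:
    """Record every individual whose step ended with a move INTO a station.

    Capture is triggered by arrival only: an individual sitting on a
    station without moving this step is not re-evaluated. Captured
    individuals stay in the population.
    """
    arrived = moved & layout.trap_cell_mask[pop.cell]
    log.passive_mask |= arrived
    return log


def apply_active_capture(
    pop: Population,
    transect: Transect,
    config: SimulationConfig,
    rng: np.random.Generator,
    log: CaptureLog,
) -> CaptureLog:
    """Detect individuals on the day's transect with per-sex probability."""
    on_transect = np.zeros(pop.N * pop.N, dtype=bool)
    on_transect[transect.cell_indices(pop.N)] = True
    present = np.flatnonzero(on_transect[pop.cell])
    if present.size:
        p_detect = np.where(
            pop.is_male[present], config.male_detectability, config.female_detectability
        )
        detected = present[rng.random(present.size) < p_detect]
        log.active_mask[detected] = True
    return log


def run_sampling_phase(
    pop: Population,
    kernel,
    layout: TrapLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CaptureLog:
    """Run the survey: ``sampling_days`` steps of movement plus both methods.

    Each day: (1) every individual takes its movement step, (2) traps
    record arrivals, (3) one active transect is drawn and searched on the
    post-movement positions. Both methods observe the same trajectory.
    """
    from .population import step_movement

    log = CaptureLog.empty(pop.size)
    for _ in range(config.sampling_days):
        moved = step_movement(pop, kernel, config, rng)
        apply_passive_capture(pop, moved, layout, log)
        transect = choose_active_transect(config, rng)
        apply_active_capture(pop, transect, config, rng, log)
    return log
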