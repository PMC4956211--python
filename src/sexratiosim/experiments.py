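"""Sweep orchestration: single replicates, sensitivity sweeps, interactions.

A sensitivity sweep varies one parameter over its standard grid while all
others stay at their defaults. An interaction sweep re-runs the
sampling-days or passive-effort sweep under fixed movement- or
detectability-asymmetry scenarios. Every replicate has its own RNG
stream (``seed + replicate_index``), so results are independent of
execution order and any subset is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .config import SimulationConfig
from .kernel import build_distance_kernel
from .population import init_population, run_burn_in
from .sampling import build_trap_layout, run_sampling_phase
from .stats import RunResult, SweepRecord, aggregate_replicates, classify_run

__all__ = [
    "SweepSpec",
    "SENSITIVITY_GRIDS",
    "MOVEMENT_SCENARIOS",
    "DETECTABILITY_SCENARIOS",
    "run_replicate",
    "run_combination",
    "run_sensitivity_sweep",
    "run_interaction_sweep",
]

# Standard value grids for the six single-parameter sensitivity sweeps:
# grid size 10..55 by 5; sampling days 35..350 by 35; male movement
# probability 0.5..0.95 by 0.05; passive effort 0.10..0.55 by 0.05;
# equal detectability 0.1..1.0 by 0.1; opposed detectabilities summing
# to 1, male from 0.1 to 0.9 by 0.1.
SENSITIVITY_GRIDS: dict[str, tuple] = {
    "grid_resolution": tuple(range(10, 56, 5)),
    "sampling_days": tuple(range(35, 351, 35)),
    "male_move_prob": tuple(round(0.5 + 0.05 * i, 2) for i in range(10)),
    "passive_effort": tuple(round(0.10 + 0.05 * i, 2) for i in range(10)),
    "equal_detectability": tuple(round(0.1 * i, 1) for i in range(1, 11)),
    "detectability_difference": tuple(
        (round(0.1 * i, 1), round(1 - 0.1 * i, 1)) for i in range(1, 10)
    ),
}

# Asymmetry scenarios for the interaction sweeps.
MOVEMENT_SCENARIOS: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9)
DETECTABILITY_SCENARIOS: tuple[tuple[float, float], ...] = (
    (0.1, 0.9),
    (0.2, 0.8),
    (0.3, 0.7),
    (0.4, 0.6),
)


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """One sweep's base configuration, varied parameter, and value grid.

    ``values=None`` selects the standard grid for the parameter. For
    interaction sweeps, ``scenario_kind`` is ``"movement"`` or
    ``"detectability"`` and ``scenarios`` (defaulting to the standard
    four) fixes the asymmetry while ``parameter`` varies.
    """

    base_config: SimulationConfig
    parameter: str
    values: tuple | None = None
    scenario_kind: str | None = None
    scenarios: tuple | None = None

    def resolved_values(self) -> tuple:
        if self.values is not None:
            return tuple(self.values)
        if self.parameter not in SENSITIVITY_GRIDS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"expected one of {sorted(SENSITIVITY_GRIDS)}"
            )
        return SENSITIVITY_GRIDS[self.parameter]


def _apply_value(config: SimulationConfig, parameter: str, value) -> SimulationConfig:
    if parameter == "equal_detectability":
        return config.replace(male_detectability=value, female_detectability=value)
    if parameter == "detectability_difference":
        de_ma, de_fe = value
        return config.replace(male_detectability=de_ma, female_detectability=de_fe)
    if parameter in {
        "grid_resolution",
        "sampling_days",
        "male_move_prob",
        "passive_effort",
    }:
        return config.replace(**{parameter: value})
    raise ValueError(f"unknown sweep parameter {parameter!r}")


def run_replicate(config: SimulationConfig, replicate_index: int) -> RunResult:
    """Run one full replicate: place, burn in, survey, classify.

    Deterministic given ``(config, replicate_index)``: the replicate owns
    the RNG stream seeded with ``config.seed + replicate_index``.
    """
    rng = np.random.default_rng(config.seed + replicate_index)
    kernel = build_distance_kernel(config.grid_resolution)
    pop = init_population(config, rng)
    layout = build_trap_layout(config, rng)
    run_burn_in(pop, kernel, config, rng)
    log = run_sampling_phase(pop, kernel, layout, config, rng)
    return classify_run(log, pop, config.alpha)


def run_combination(config: SimulationConfig) -> SweepRecord:
    """Run all replicates of one parameter combination and tally them."""
    results = [run_replicate(config, i) for i in range(config.replicates)]
    return aggregate_replicates(results, config)


def _seed_stride(config: SimulationConfig) -> int:
    return max(1000, config.replicates)


def run_sensitivity_sweep(spec: SweepSpec) -> list[SweepRecord]:
    """One record per grid value of a single-parameter sweep.

    Each combination gets a distinct base seed (``seed + stride * index``)
    so replicate streams never collide across combinations.
    """
    stride = _seed_stride(spec.base_config)
    records = []
    for i, value in enumerate(spec.resolved_values()):
        cfg = _apply_value(spec.base_config, spec.parameter, value)
        cfg = cfg.replace(seed=spec.base_config.seed + stride * i)
        records.append(run_combination(cfg))
    return records


def run_interaction_sweep(spec: SweepSpec) -> list[SweepRecord]:
    """Cross a days or effort sweep with asymmetry scenarios.

    ``spec.parameter`` must be ``sampling_days`` or ``passive_effort``;
    each scenario fixes either the male movement probability
    (``scenario_kind="movement"``) or the (male, female) detectability
    pair (``scenario_kind="detectability"``). Records are ordered
    scenario-major.
    """
    if spec.parameter not in {"sampling_days", "passive_effort"}:
        raise ValueError(
            "interaction sweeps vary 'sampling_days' or 'passive_effort', "
            f"got {spec.parameter!r}"
        )
    if spec.scenario_kind == "movement":
        scenarios: Sequence = spec.scenarios or MOVEMENT_SCENARIOS
        scenario_param = "male_move_prob"
    elif spec.scenario_kind == "detectability":
        scenarios = spec.scenarios or DETECTABILITY_SCENARIOS
        scenario_param = "detectability_difference"
    else:
        raise ValueError("scenario_kind must be 'movement' or 'detectability'")

    values = spec.resolved_values()
    stride = _seed_stride(spec.base_config)
    records = []
    combo = 0
    for scen in scenarios:
        scen_cfg = _apply_value(spec.base_config, scenario_param, scen)
        for value in values:
            cfg = _apply_value(scen_cfg, spec.parameter, value)
            cfg = cfg.replace(seed=spec.base_config.seed + stride * combo)
            records.append(run_combination(cfg))
            combo += 1
    return records
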