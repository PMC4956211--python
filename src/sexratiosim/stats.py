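"""Sex-ratio estimation, chi-square classification, and replicate tallies.

Each replicate yields unique-capture counts per sex for each method. A
Pearson chi-square goodness-of-fit test against the true 1:1 split (df=1,
no continuity correction) classifies the recovered ratio as male-biased,
female-biased, or unbiased; a method that captured nothing is classified
``no_data`` rather than folded into the unbiased tally.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Literal, Sequence

from scipy import stats as sps

from .config import SimulationConfig
from .population import Population
from .sampling import CaptureLog

__all__ = [
    "Classification",
    "MethodOutcome",
    "RunResult",
    "SweepRecord",
    "chisq_gof",
    "classify_counts",
    "classify_run",
    "aggregate_replicates",
]

Classification = Literal["male_biased", "female_biased", "unbiased", "no_data"]


def chisq_gof(male_count: int, female_count: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of observed sex counts against a 1:1 split.

    statistic = (M - T/2)^2 / (T/2) + (F - T/2)^2 / (T/2),  T = M + F,
    with the p-value from the chi-square distribution with one degree of
    freedom and no continuity correction.

    Raises
    ------
    ValueError
        If both counts are zero (the test is undefined; callers should
        classify such a replicate as ``no_data``).
    """
    if male_count < 0 or female_count < 0:
        raise ValueError("counts must be non-negative")
    total = male_count + female_count
    if total == 0:
        raise ValueError("chi-square test undefined for zero captures")
    expected = total / 2.0
    stat = (male_count - expected) ** 2 / expected + (female_count - expected) ** 2 / expected
    return stat, float(sps.chi2.sf(stat, df=1))


@dataclasses.dataclass(frozen=True)
class MethodOutcome:
    """One method's unique-capture counts, test result, and class label."""

    male_captures: int
    female_captures: int
    statistic: float  # NaN when no_data
    p_value: float  # NaN when no_data
    classification: Classification


def classify_counts(male_count: int, female_count: int, alpha: float) -> MethodOutcome:
    """Classify a pair of unique-capture counts.

    male_biased iff p < alpha and M > F; female_biased iff p < alpha and
    F > M; unbiased iff p >= alpha; no_data iff both counts are zero.
    (p < alpha with M == F cannot occur: equal counts give statistic 0.)
    """
    if male_count + female_count == 0:
        return MethodOutcome(0, 0, math.nan, math.nan, "no_data")
    stat, p = chisq_gof(male_count, female_count)
    if p < alpha:
        label: Classification = "male_biased" if male_count > female_count else "female_biased"
    else:
        label = "unbiased"
    return MethodOutcome(male_count, female_count, stat, p, label)


@dataclasses.dataclass(frozen=True)
class RunResult:
    """Per-replicate outcome: one :class:`MethodOutcome` per method."""

    passive: MethodOutcome
    active: MethodOutcome


def classify_run(log: CaptureLog, pop: Population, alpha: float) -> RunResult:
    """Count unique captures per sex and method, then classify each method."""
    pas_m = int((log.passive_mask & pop.is_male).sum())
    pas_f = int((log.passive_mask & ~pop.is_male).sum())
    act_m = int((log.active_mask & pop.is_male).sum())
    act_f = int((log.active_mask & ~pop.is_male).sum())
    return RunResult(
        passive=classify_counts(pas_m, pas_f, alpha),
        active=classify_counts(act_m, act_f, alpha),
    )


@dataclasses.dataclass(frozen=True)
class SweepRecord:
    """Classification tallies for one parameter combination.

    Column names follow the conventional sweep-table schema: R (grid
    size), Days, SaEf (passive effort), Mov (male movement probability),
    DeMa / DeFe (detectabilities), then counts of replicates whose
    passive-sampling (PS) and active-search (AS) estimates were
    male-biased, female-biased, unbiased, or produced no captures.
    """

    R: int
    Days: int
    SaEf: float
    Mov: float
    DeMa: float
    DeFe: float
    MaPS: int
    FePS: int
    UnbiasedPS: int
    NoDataPS: int
    MaAS: int
    FeAS: int
    UnbiasedAS: int
    NoDataAS: int

    def __post_init__(self) -> None:
        ps = self.MaPS + self.FePS + self.UnbiasedPS + self.NoDataPS
        as_ = self.MaAS + self.FeAS + self.UnbiasedAS + self.NoDataAS
        if ps != as_:
            raise ValueError("per-method tallies disagree on the replicate count")

    @property
    def replicates(self) -> int:
        return self.MaPS + self.FePS + self.UnbiasedPS + self.NoDataPS

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_CLASS_TO_COLUMN = {
    "male_biased": "Ma",
    "female_biased": "Fe",
    "unbiased": "Unbiased",
    "no_data": "NoData",
}


def aggregate_replicates(
    results: Sequence[RunResult] | Iterable[RunResult],
    config: SimulationConfig,
) -> SweepRecord:
    """Tally replicate classifications into one sweep-table row.

    All results must come from the same parameter combination (the caller
    guarantees this; the record stores the combination once).
    """
    tallies = {f"{c}{m}": 0 for c in _CLASS_TO_COLUMN.values() for m in ("PS", "AS")}
    n = 0
    for res in results:
        n += 1
        tallies[_CLASS_TO_COLUMN[res.passive.classification] + "PS"] += 1
        tallies[_CLASS_TO_COLUMN[res.active.classification] + "AS"] += 1
    if n == 0:
        raise ValueError("cannot aggregate zero replicates")
    return SweepRecord(
        R=config.grid_resolution,
        Days=config.sampling_days,
        SaEf=config.passive_effort,
        Mov=config.male_move_prob,
        DeMa=config.male_detectability,
        DeFe=config.female_detectability,
        **tallies,
    )
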