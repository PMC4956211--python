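"""Sweep-table CSV output, read-back, and summary plots."""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .stats import SweepRecord

__all__ = ["SWEEP_COLUMNS", "write_sweep_csv", "read_sweep_csv", "plot_summary"]

SWEEP_COLUMNS = [
    "R", "Days", "SaEf", "Mov", "DeMa", "DeFe",
    "MaPS", "FePS", "UnbiasedPS", "NoDataPS",
    "MaAS", "FeAS", "UnbiasedAS", "NoDataAS",
]

_PLOT_X = {
    "asymmetry-curves": ("Mov", "DeMa"),
    "days-curves": ("Days",),
    "effort-curves": ("SaEf",),
}


def records_to_frame(records: Sequence[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records], columns=SWEEP_COLUMNS)


def write_sweep_csv(
    records: Sequence[SweepRecord],
    path: str | Path,
    seed: int | None = None,
) -> Path:
    """Write sweep records as CSV plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) records the base seed, package
    version and timestamp — enough provenance to re-run bit-identically.
    """
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    meta = {
        "seed": seed,
        "version": __version__,
        "rows": len(records),
        "written": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    """Read a sweep table back; validates the column schema."""
    df = pd.read_csv(path)
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sweep columns {missing}")
    return df[SWEEP_COLUMNS]


def plot_summary(
    records: Sequence[SweepRecord],
    kind: str,
    path: str | Path,
) -> Path:
    """Plot unbiased-replicate counts per method against the swept parameter.

    ``kind`` is one of ``asymmetry-curves`` (x = movement probability or
    male detectability, whichever varies), ``days-curves`` (x = sampling
    days) or ``effort-curves`` (x = passive effort). Red circles: passive
    capture; blue squares: active search.
    """
    if not records:
        raise ValueError("no records to plot")
    if kind not in _PLOT_X:
        raise ValueError(f"unknown plot kind {kind!r}; expected one of {sorted(_PLOT_X)}")
    df = records_to_frame(records)
    candidates = _PLOT_X[kind]
    x_col = next((c for c in candidates if df[c].nunique() > 1), candidates[0])

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(df[x_col], df["UnbiasedPS"], "o-", color="red", label="passive capture")
    ax.plot(df[x_col], df["UnbiasedAS"], "s-", color="blue", label="active search")
    ax.set_xlabel(x_col)
    ax.set_ylabel("replicates with unbiased sex ratio")
    ax.set_ylim(bottom=0)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
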