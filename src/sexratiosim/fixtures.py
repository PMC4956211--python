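"""Small frozen configurations for tests and demos."""

from __future__ import annotations

from .config import SimulationConfig

__all__ = ["make_fixture"]

_FIXTURES = {
    # 100 individuals, seconds of work: smoke tests and examples.
    "tiny": SimulationConfig(
        grid_resolution=5,
        sampling_days=10,
        burn_in_steps=25,
        replicates=5,
        seed=20160721,
    ),
    # 400 individuals, full-length survey: property tests.
    "small": SimulationConfig(
        grid_resolution=10,
        sampling_days=100,
        burn_in_steps=100,
        replicates=20,
        seed=9159736,
    ),
}


def make_fixture(size: str = "tiny") -> SimulationConfig:
    """Return a frozen demo configuration (``"tiny"`` or ``"small"``)."""
    try:
        return _FIXTURES[size]
    except KeyError:
        raise ValueError(f"unknown fixture size {size!r}; expected one of {sorted(_FIXTURES)}")
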