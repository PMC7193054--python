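import numpy as np
import pytest

from zfscreen import SimulationConfig, VelocityTrace


def child_seed(*parts: int) -> np.random.SeedSequence:
    """Deterministic child seed stream for test replicates."""
    return np.random.SeedSequence(list(parts))


@pytest.fixture(scope="session")
def cfg() -> SimulationConfig:
    """Default study conditions."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def fast_cfg() -> SimulationConfig:
    """Short epochs and light event loads for plumbing tests."""
    return SimulationConfig(
        epoch_duration=60.0,
        vehicle_interictal_count_range=(15, 40),
        vehicle_ictal_count_range=(1, 3),
    )


def constant_velocity_trace(
    value: float,
    epoch: str = "experimental",
    duration: float = 600.0,
    fs: float = 25.0,
    fish_id: str = "f0",
) -> VelocityTrace:
    n = int(round(duration * fs))
    return VelocityTrace(
        well_id="W0",
        fish_id=fish_id,
        epoch=epoch,
        sampling_rate=fs,
        samples=np.full(n, float(value)),
    )


def constant_pairs(baseline: float, experimental: float, n_fish: int = 6):
    """Paired constant-velocity traces for exact percent-change constructions."""
    return [
        (
            constant_velocity_trace(baseline, "baseline", fish_id=f"f{i}"),
            constant_velocity_trace(experimental, "experimental", fish_id=f"f{i}"),
        )
        for i in range(n_fish)
    ]
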