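import numpy as np
import pytest

from helixmetrics.synthetic_data import (
    AngularDistribution,
    SyntheticSpec,
    generate_trajectory,
    structural_indices,
)
from helixmetrics.trajectory_io import Frame, Trajectory, AtomRecord


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A cheap 30-frame system used by several suites."""
    return SyntheticSpec(
        n_frames=30,
        n_waters=300,
        seed=42,
        tilt_distribution=AngularDistribution(mean_deg=27.6, sd_deg=7.0),
        azimuth_distribution=AngularDistribution(mean_deg=20.0, sd_deg=15.0),
    )


@pytest.fixture(scope="session")
def small_system(small_spec):
    return generate_trajectory(small_spec)


@pytest.fixture(scope="session")
def small_indices(small_spec):
    return structural_indices(small_spec)


@pytest.fixture(scope="session")
def written_system(small_spec, tmp_path_factory):
    """The same small system written to PDB + DCD files."""
    out = tmp_path_factory.mktemp("written")
    return generate_trajectory(small_spec, out_dir=out, label="small")


def single_atom_trajectory(n_frames: int, dt: float, t0: float | None = None) -> Trajectory:
    """Minimal trajectory for frame-accounting tests (1 atom)."""
    topo = [AtomRecord(0, "CA", 1, "ALA")]
    if t0 is None:
        t0 = dt
    frames = [
        Frame(np.zeros((1, 3)) + i, time=t0 + i * dt, box=np.array([50.0, 50.0, 50.0]))
        for i in range(n_frames)
    ]
    return Trajectory(topology=topo, frames=frames, nominal_dt=dt)
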