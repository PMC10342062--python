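"""Shared fixtures: small synthetic systems generated at test time."""

import numpy as np
import pytest

from aquaflux import (
    ChannelSpec,
    Topology,
    Trajectory,
    simulate_channel_water,
)


def make_water_trajectory(z_paths, box=(20.0, 20.0, 60.0), dt_frame=1.0):
    """Trajectory of waters following prescribed z paths (x = y = 0).

    ``z_paths``: array (n_frames, n_molecules).
    """
    z = np.asarray(z_paths, float)
    coords = np.zeros((z.shape[0], z.shape[1], 3))
    coords[:, :, 2] = z
    top = Topology.from_arrays(
        names=["O"] * z.shape[1],
        segments=["water"] * z.shape[1],
        masses=np.full(z.shape[1], 18.0153),
    )
    return Trajectory(
        coordinates=coords,
        box=np.tile(box, (z.shape[0], 1)),
        dt_frame=dt_frame,
        topology=top,
    )


@pytest.fixture(scope="session")
def channel_traj():
    """A medium flat-potential channel run shared across tests (~10 s)."""
    spec = ChannelSpec(
        box=(30.0, 30.0, 70.0),
        channel_radius=5.0,
        n_waters=120,
        dt=0.1,
        n_steps=100_000,
        sample_every=10,
        seed=2024,
    )
    return simulate_channel_water(spec)
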