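import numpy as np
import pandas as pd
import pytest

from meiomove.io import align_time, derive_velocities
from meiomove.synthetic import SyntheticConfig, generate_dataset


def make_tracks(specs, group="g1"):
    """Build a track table from {particle: (x, y[, t])} arrays."""
    frames = []
    for pid, arrs in specs.items():
        x, y = np.asarray(arrs[0], float), np.asarray(arrs[1], float)
        t = np.asarray(arrs[2], float) if len(arrs) > 2 else np.arange(len(x), dtype=float)
        frames.append(pd.DataFrame({
            "group_id": group, "particle_id": pid, "time_min": t, "x": x, "y": y,
        }))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_tracks_per_type=6, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    table, truths = generate_dataset(small_config)
    return align_time(table), truths


@pytest.fixture(scope="session")
def velocity_dataset(small_dataset):
    table, truths = small_dataset
    return derive_velocities(table), truths
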