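import numpy as np
import pandas as pd
import pytest

from herdwatch.synthetic import (Landscape, RawSensorTrack, SimulationConfig,
                                 generate_landscape)

SMALL_SPECIES = {"zebra": 6, "wildebeest": 0, "eland": 0, "impala": 0}


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(1, extent_m=2000.0, cell_m=10.0)


@pytest.fixture()
def sim_config():
    return SimulationConfig(n_per_species=dict(SMALL_SPECIES))


def constant_suitability_landscape(value: float, extent_m=2000.0,
                                   cell_m=10.0) -> Landscape:
    base = generate_landscape(3, extent_m=extent_m, cell_m=cell_m)
    suit = {k: np.full_like(v, value) for k, v in base.suitability.items()}
    return Landscape(origin=base.origin, cell_size=base.cell_size,
                     tree_cover=base.tree_cover, elevation=base.elevation,
                     suitability=suit)


def make_raw(fix_times, fixes, animal_id="a0", species="zebra",
             odba=None) -> RawSensorTrack:
    """Hand-built sensor track; ODBA windows cover the fix span if given.

    ``odba`` may be a scalar (constant window mean) or a DataFrame.
    """
    fix_times = np.asarray(fix_times, dtype=float)
    fixes = np.asarray(fixes, dtype=float)
    if odba is None or np.isscalar(odba):
        starts = np.arange(fix_times[0], fix_times[-1] + 15.0, 15.0)
        mean = float(odba) if odba is not None else 0.2
        windows = pd.DataFrame({"window_start": starts, "mean": mean,
                                "max": mean * 1.5, "variance": 0.001})
    else:
        windows = odba
    return RawSensorTrack(animal_id=animal_id, species=species,
                          fix_times=fix_times, fixes=fixes,
                          odba_windows=windows)


def noisy_walk_raw(rng, n_fixes=40, dt=120.0, speed=0.4, noise_sd=10.0,
                   start=(1000.0, 1000.0), spike_every=None):
    """Correlated-walk truth sampled at a regular cadence with GPS noise."""
    heading = rng.uniform(-np.pi, np.pi)
    pos = np.array(start, dtype=float)
    truth = [pos.copy()]
    for _ in range(n_fixes - 1):
        heading += rng.normal(0, 0.3)
        pos = pos + dt * speed * np.array([np.cos(heading), np.sin(heading)])
        truth.append(pos.copy())
    truth = np.asarray(truth)
    fixes = truth + rng.normal(0, noise_sd, truth.shape)
    if spike_every:
        for i in range(spike_every, n_fixes - 1, spike_every):
            ang = rng.uniform(-np.pi, np.pi)
            mag = rng.uniform(600, 1200)
            fixes[i] += mag * np.array([np.cos(ang), np.sin(ang)])
    times = np.arange(n_fixes) * dt
    return times, truth, fixes
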