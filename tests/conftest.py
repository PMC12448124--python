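import dataclasses

import numpy as np
import pytest

import photokin as pk


@pytest.fixture(scope="session")
def fap560_spec():
    return pk.build_preset("fap560")


@pytest.fixture(scope="session")
def fap560_data(fap560_spec):
    """The default 560-nm synthetic dataset: noise 0.1 mOD, seed 1."""
    return pk.simulate_ta(fap560_spec)


@pytest.fixture(scope="session")
def fap560_fit(fap560_data):
    """Full multi-start target-analysis fit of the default 560-nm dataset."""
    return pk.fit_global(
        fap560_data, pk.model_for_preset("fap560"),
        options=pk.FitOptions(n_starts=5, seed=0),
    )


@pytest.fixture(scope="session")
def fap560_multiseed_fits(fap560_spec):
    """Fits of 20 noise realizations of the 560-nm dataset (seeds 1..20)."""
    model = pk.model_for_preset("fap560")
    fits = []
    for seed in range(1, 21):
        data = pk.simulate_ta(dataclasses.replace(fap560_spec, seed=seed))
        fits.append(
            pk.fit_global(data, model, options=pk.FitOptions(n_starts=2, seed=0))
        )
    return fits


@pytest.fixture(scope="session")
def toy_traj_stepped():
    """Toy trajectory with the probe stepping 4.2 -> 6.5 A and water
    occupancy coupled to the probe distance."""
    sched = np.concatenate([np.full(30, 4.2), np.full(30, 6.5)])
    cfg = pk.ToyTrajectoryConfig(
        n_frames=60, probe_distance_schedule=sched, mean_occupancy=4.0,
        jitter_sigma=0.15, seed=3, occupancy_coupling=1.0,
    )
    return pk.make_toy_trajectory(cfg)
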