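import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

TABLE1_CSV = """subject,trial,choice,rt,item_value_0,item_value_1,item_value_2,gaze_0,gaze_1,gaze_2,speed
0,0,0,2.056,5,1,3,0.16,0.62,0.22,fast
0,1,2,3.685,3,6,9,0.44,0.22,0.34,slow
1,0,1,1.8,2,7,4,0.3,0.4,0.3,fast
1,1,0,2.4,8,3,5,0.5,0.3,0.2,slow
"""


@pytest.fixture
def table1_path(tmp_path):
    path = tmp_path / "table1.csv"
    path.write_text(TABLE1_CSV)
    return path


@pytest.fixture(scope="session")
def biased_sim():
    """4 subjects x 250 trials with known parameters (two strongly gaze-biased,
    one moderate, one without gaze bias)."""
    from gazerace.simulate import GroupSpec, simulate_group

    spec = GroupSpec(
        kind="individual", n_individuals=4, n_trials=250, n_items=3,
        parameters={"v": [0.7, 0.8, 0.65, 0.75],
                    "gamma": [-0.5, 0.3, 0.1, 1.0],
                    "sigma": [0.25, 0.28, 0.24, 0.26],
                    "tau": [1.0, 1.2, 0.9, 1.1]},
        seed=42)
    return simulate_group(spec)


@pytest.fixture(scope="session")
def individual_fit(biased_sim):
    from gazerace.inference import build_model, fit_mcmc

    model = build_model(biased_sim.data, kind="individual", name="glam_bias")
    return fit_mcmc(model, draws=800, tune=1000, chains=2, seed=7)


@pytest.fixture(scope="session")
def grouped_sim():
    """Two groups differing only in the gaze bias, for contrast tests."""
    from gazerace.simulate import GroupSpec, simulate_group

    labels = ["ctrl"] * 8 + ["pat"] * 8
    spec = GroupSpec(
        kind="hierarchical", n_individuals=16, n_trials=60, n_items=3,
        parameters={"gamma": {"mu": {"ctrl": 0.7, "pat": -0.4}, "sd": 0.2},
                    "v": {"mu": 0.7, "sd": 0.15},
                    "sigma": {"mu": 0.27, "sd": 0.05},
                    "tau": {"mu": 1.0, "sd": 0.3}},
        group_labels=labels, seed=13)
    return simulate_group(spec)


@pytest.fixture(scope="session")
def hierarchical_fit(grouped_sim):
    from gazerace.inference import build_model, fit_mcmc

    model = build_model(grouped_sim.data, kind="hierarchical",
                        depends_on={"gamma": "group"}, name="hglam")
    return fit_mcmc(model, draws=1000, tune=1500, chains=2, seed=19)


def uniform_random_table(rng, n_trials=300, n_items=3, n_subjects=1):
    """A table whose choices are uniformly random and independent of the data."""
    n = n_trials * n_subjects
    values = rng.integers(1, 11, (n, n_items)).astype(float)
    gazes = rng.dirichlet(np.ones(n_items), n)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subjects), n_trials),
        "trial": np.tile(np.arange(n_trials), n_subjects),
        "choice": rng.integers(0, n_items, n),
        "rt": rng.uniform(0.5, 3.0, n),
    })
    for i in range(n_items):
        df[f"item_value_{i}"] = values[:, i]
    for i in range(n_items):
        df[f"gaze_{i}"] = gazes[:, i]
    return df
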