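import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fishid import datasets, preprocessing

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def analysis_scale(raw):
    """Raw trial table -> analysis-scale traits without SDU standardization
    (the generator's trait scale is the analysis scale by construction)."""
    sdu, _ = preprocessing.preprocess(raw, standardize=False)
    return sdu


@pytest.fixture(scope="session")
def xh_spec():
    """Moderate-size X. hellerii generating spec used across model tests."""
    return datasets.default_species_spec("Xiphophorus hellerii",
                                         n_individuals=120, trials=4)


@pytest.fixture(scope="session")
def xh_table(xh_spec):
    return analysis_scale(datasets.simulate_species(xh_spec, seed=101))


@pytest.fixture(scope="session")
def well_conditioned_spec():
    """Interior-parameter spec (ID far from singular) for bias-sensitive checks."""
    id_mat = 0.3 * np.eye(4) + 0.1
    r_mat = 0.6 * np.eye(4) + 0.15
    return datasets.SpeciesSpec(
        name="Synthetic interior", n_individuals=200, trials_per_individual=4,
        group_size=8, mean_sl=30.0,
        trait_means=np.array([100.0, 40.0, 55.0, 8.0]),
        true_ID=id_mat, true_R=r_mat,
        repeat_effects=datasets.default_repeat_effects(4),
        order_slope=datasets.DEFAULT_ORDER_SLOPE,
    ).validate()


def simulate_two_trait(n_ind, n_trials, G, R, seed, beta_repeat=0.05,
                       beta_order=-0.02, labels=("y1", "y2")):
    """Minimal two-trait random-intercept simulator for engine-level tests."""
    rng = np.random.default_rng(seed)
    T = len(labels)
    u = rng.multivariate_normal(np.zeros(T), G, size=n_ind, method="eigh")
    e = rng.multivariate_normal(np.zeros(T), R, size=(n_ind, n_trials))
    order = np.arange(n_ind) % 6 + 1
    rep = np.arange(1, n_trials + 1)
    y = (u[:, None, :] + e
         + beta_repeat * (rep - 1)[None, :, None]
         + beta_order * order[:, None, None])
    rows = {
        "fish_id": np.repeat([f"f{i:04d}" for i in range(n_ind)], n_trials),
        "group": np.repeat(np.arange(n_ind) // 6 + 1, n_trials),
        "order_in_group": np.repeat(order, n_trials),
        "repeat": np.tile(rep, n_ind),
    }
    tab = pd.DataFrame(rows)
    flat = y.reshape(n_ind * n_trials, T)
    for t, lab in enumerate(labels):
        tab[lab] = flat[:, t]
    tab["species"] = "sim"
    return tab
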