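import numpy as np
import pandas as pd
import pytest

import foodmsm as fm

#: published baseline transition intensities (month^-1) used as the
#: reference generator throughout the tests
TABLE_RATES = {
    (1, 2): 0.273804,
    (1, 3): 0.001641,
    (1, 4): 0.000326,
    (2, 1): 0.440019,
    (2, 3): 0.322575,
    (2, 4): 0.000148,
    (3, 1): 0.020105,
    (3, 2): 0.394426,
    (3, 4): 0.116817,
    (4, 1): 0.002548,
    (4, 2): 0.002232,
    (4, 3): 0.766246,
}


@pytest.fixture(scope="session")
def reference_Q() -> fm.IntensityMatrix:
    return fm.build_intensity_matrix(TABLE_RATES)


@pytest.fixture()
def toy_panel() -> fm.PanelDataset:
    """Three subjects, hand-checkable."""
    frame = pd.DataFrame(
        {
            "id": [1, 1, 1, 2, 2, 3, 3],
            "time": [0.0, 1.0, 2.0, 0.0, 2.0, 0.0, 3.0],
            "state": [1, 2, 2, 3, 1, 4, 4],
            "sex_female": 0,
            "age_ge40": 1,
            "urban": 0,
            "employed": 1,
            "assisted": 0,
            "income_reduced": 0,
        }
    )
    return fm.PanelDataset(frame)


@pytest.fixture(scope="session")
def sim_panel() -> fm.SimulatedPanel:
    """Mid-sized synthetic panel under the reference dynamics."""
    return fm.simulate_panel(fm.SimulationDesign(n_subjects=800, seed=11))


@pytest.fixture(scope="session")
def recovery_fit() -> tuple:
    """One large simulate-then-fit under the true forward-adjacent model.

    Shared across tests that interrogate a converged covariate fit.
    """
    design = fm.SimulationDesign(n_subjects=2000, seed=20200501)
    params, structure = design.resolved_parameters()
    ds, _ = fm.drop_single_observation_subjects(fm.simulate_panel(design).dataset)
    fit = fm.fit_msm(ds, structure)
    return design, ds, fit


def random_generator(rng: np.random.Generator, scale: float = 1.0) -> fm.IntensityMatrix:
    """A random valid 4-state generator with all 12 rates positive."""
    rates = {
        (i, j): float(scale * rng.uniform(0.05, 1.0))
        for i in range(1, 5)
        for j in range(1, 5)
        if i != j
    }
    return fm.build_intensity_matrix(rates)
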