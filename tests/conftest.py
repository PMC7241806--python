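"""Shared fixtures: small deterministic datasets built in memory."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from refstab.datamodel import RQMatrix
from refstab.preprocess import aggregate_replicates, relative_quantity
from refstab.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic study: 7 groups x 8 samples, 10 genes, 2 plates."""
    cfg = SimConfig()
    reps, eff, truth = simulate_dataset(cfg, seed=7)
    return cfg, reps, eff, truth


@pytest.fixture(scope="session")
def sim_rq(sim_default):
    """Plate-corrected RQ matrix of the default synthetic study."""
    from refstab.preprocess import plate_factor_correction

    _, reps, eff, _ = sim_default
    cq = aggregate_replicates(reps)
    rq = relative_quantity(cq, eff, mode="nq")
    corrected, _ = plate_factor_correction(rq)
    return corrected


def make_rq(values: np.ndarray, genes, groups=None, plates=None) -> RQMatrix:
    samples = [f"S{i + 1}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=samples, columns=list(genes))
    grp = pd.Series(groups if groups is not None else ["all"] * len(samples), index=samples)
    plt = pd.Series(plates, index=samples) if plates is not None else None
    return RQMatrix(values=frame, groups=grp, plates=plt)


@pytest.fixture
def toy_rq_abc():
    """geNorm toy: A = (1,2,4,8), B = 2A, C = constant 1."""
    vals = np.array(
        [[1.0, 2.0, 1.0], [2.0, 4.0, 1.0], [4.0, 8.0, 1.0], [8.0, 16.0, 1.0]]
    )
    return make_rq(vals, ["A", "B", "C"])
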