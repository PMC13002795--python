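import numpy as np
import pandas as pd
import pytest

from ncd2.datasets import load_example_cross_means, load_example_mean_squares
from ncd2.simulate import SimulationConfig, simulate_trial
from ncd2.trial import TraitCatalog, TrialDataset


@pytest.fixture(scope="session")
def example_means():
    return load_example_cross_means()


@pytest.fixture(scope="session")
def example_ms():
    return load_example_mean_squares()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)


def make_trial(p=2, q=2, r=2, seed=0, **kw):
    """Small random complete trial used across test modules."""
    cfg = SimulationConfig(
        mu=kw.pop("mu", 10.0),
        sigma2_f=kw.pop("sigma2_f", 2.0),
        sigma2_m=kw.pop("sigma2_m", 1.5),
        sigma2_fm=kw.pop("sigma2_fm", 1.0),
        sigma2_block=kw.pop("sigma2_block", 0.5),
        sigma2_e=kw.pop("sigma2_e", 1.0),
        p=p,
        q=q,
        r=r,
        seed=seed,
        **kw,
    )
    return simulate_trial(cfg, trait_names=("y",))


@pytest.fixture()
def small_trial():
    return make_trial(p=3, q=3, r=3, seed=11)


def trial_from_cells(cells, r=2, trait="y"):
    """Build a trial from {(female, male): [block values]} mappings."""
    rows = []
    for (f, m), values in cells.items():
        for k, v in enumerate(values):
            rows.append({"female": f, "male": m, "block": f"B{k + 1}", trait: float(v)})
    return TrialDataset(pd.DataFrame(rows), TraitCatalog((trait,)))
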