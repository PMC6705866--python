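import warnings

import numpy as np
import pandas as pd
import pytest

import bfamet as bf

warnings.filterwarnings("ignore", category=RuntimeWarning, module="bfamet")


def toy_frame(missing_cells=()):
    """3 genotypes x 2 environments x 2 blocks complete table (12 rows)."""
    rows = []
    value = 0.0
    for env in ("E1", "E2"):
        for blk in ("B1", "B2"):
            for gen in ("G1", "G2", "G3"):
                if (gen, env) in missing_cells:
                    continue
                value += 0.7
                rows.append((gen, env, blk, round(value % 5 + 0.1, 3)))
    return pd.DataFrame(rows, columns=["gen", "env", "rep", "y"])


@pytest.fixture
def toy_df():
    return toy_frame()


@pytest.fixture
def toy_data(toy_df):
    return bf.METDataset(
        toy_df.rename(columns={"gen": "genotype", "env": "environment",
                               "rep": "block", "y": "value"})
    )


@pytest.fixture(scope="session")
def sim_default():
    """One default-design realization with known truth (fixture seed 11)."""
    return bf.simulate_met(bf.SimulationDesign(), seed=11)


@pytest.fixture(scope="session")
def chain_full(sim_default):
    """Full-rank fit of the default realization: 10,000 scans, 2,000 burn-in,
    thinning 2 (4,000 retained draws)."""
    data, _ = sim_default
    config = bf.SamplerConfig(
        k=data.p, iterations=10_000, burn_in=2_000, thin=2, seed=11,
        full_rank=True,
    )
    return bf.run_gibbs(data, config)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast trial for sampler plumbing tests: 8 genotypes x 3 envs."""
    design = bf.SimulationDesign(
        m=8, p=3, q=2, group_sizes=(2, 2, 4),
        residual_variances=(0.5, 1.0, 2.0),
    )
    return bf.simulate_met(design, seed=4)
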