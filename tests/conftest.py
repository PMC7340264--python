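import numpy as np
import pytest

import pairladder as pl


@pytest.fixture(scope="session")
def cubic_cell():
    return pl.UnitCell(10.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def small_config():
    """Fast study conditions for unit tests: few reflections, same physics."""
    return pl.GeneratorConfig(
        cell=pl.UnitCell(12.0, 13.0, 14.0),
        n_atoms=15,
        d_min=1.6,
        d_info=2.0,
        multiplicity=4,
        flag_sets=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """(truth, merged, unmerged, degraded start) for the small conditions."""
    truth = pl.generate_truth(small_config)
    merged, unmerged = pl.generate_data(truth, small_config)
    start = pl.degrade_model(truth, small_config)
    return truth, merged, unmerged, start


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Noise-free single-observation data equal to the truth's |Fc|."""
    cfg = pl.GeneratorConfig(
        cell=pl.UnitCell(12.0, 13.0, 14.0),
        n_atoms=15,
        d_min=1.6,
        d_info=1.6,
        transition=0.0,
        multiplicity=1,
        noise_rel=0.0,
        noise_shell=0.0,
        flag_sets=10,
        seed=7,
    )
    truth = pl.generate_truth(cfg)
    merged, unmerged = pl.generate_data(truth, cfg)
    return cfg, truth, merged, unmerged


def random_unmerged(rng, n_obs=40, cell=None, d_min=1.2):
    """Random unmerged set with mixed multiplicities for oracle tests."""
    cell = cell or pl.UnitCell(10.0, 11.0, 12.0)
    uniq = pl.reflections.enumerate_unique_indices(cell, d_min)
    rows, ints, sigs = [], [], []
    while len(rows) < n_obs:
        ix = rng.integers(0, len(uniq))
        mult = int(rng.integers(1, 4))
        base = rng.uniform(1.0, 100.0)
        for _ in range(mult):
            rows.append(uniq[ix])
            ints.append(base + rng.normal(0, 5.0))
            sigs.append(rng.uniform(0.5, 3.0))
    rows, ints, sigs = rows[:n_obs], ints[:n_obs], sigs[:n_obs]
    return pl.UnmergedSet(cell, np.array(rows), np.array(ints), np.array(sigs))
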