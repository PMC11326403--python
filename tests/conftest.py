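import numpy as np
import pandas as pd
import pytest

from apaclock import io as aio
from apaclock import sim


@pytest.fixture(scope="session")
def design():
    """The default 55-library study design."""
    return sim.SimDesign(reads_per_library=5000, seed=0)


@pytest.fixture(scope="session")
def design_table(design):
    return design.design_table()


@pytest.fixture(scope="session")
def small_genome():
    """A small deterministic genome with a mitochondrial contig."""
    cfg = sim.GenomeConfig(include_mito=True)
    fasta, gtf, models = sim.simulate_genome(8, seed=11, config=cfg)
    return fasta, gtf, models


@pytest.fixture(scope="session")
def small_counts(small_genome, design):
    _, _, models = small_genome
    models = sim.scale_baselines(models, design.reads_per_library)
    signals = sim.assign_signals(models, seed=12)
    counts, truth = sim.simulate_counts(models, signals, design)
    return models, signals, counts, truth


def nb_draws(rng, mu, n, phi=0.05):
    """Gamma-Poisson NB sampler used by simulation-based tests."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    lam = np.where(mu > 0, rng.gamma(1.0 / phi, mu * phi), 0.0)
    return rng.poisson(lam)
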