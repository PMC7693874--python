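import numpy as np
import pytest

from plastiqtl import io as pio
from plastiqtl import simulate as sim


@pytest.fixture(scope="session")
def small_cross():
    """300 segregants, 4 chromosomes x 50 markers — quick shared fixture."""
    config = sim.SimConfig(
        n_segregants=300,
        chromosomes=tuple(sim.ChromosomeSpec(50, 300.0, 750_000) for _ in range(4)),
        n_environments=6,
        seed=42,
        h2_polygenic=0.3,
    )
    genotypes = sim.simulate_cross(config)
    phenos, truth = sim.simulate_phenotypes(genotypes, config)
    return config, genotypes, phenos, truth


def toy_genotypes(values, positions=None, chrom=None, ids=None):
    """Build a GenotypeMatrix from a literal array."""
    values = np.asarray(values)
    n, m = values.shape
    positions = positions if positions is not None else 1000 * (np.arange(m) + 1)
    chrom = chrom if chrom is not None else ["chr1"] * m
    ids = ids if ids is not None else [f"s{i}" for i in range(n)]
    mp = pio.MarkerMap(
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.array(chrom, dtype=object),
        np.array(positions, dtype=np.int64),
    )
    return pio.GenotypeMatrix(values, np.array(ids, dtype=object), mp)


def toy_phenotypes(values, labels=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, e = values.shape
    labels = labels if labels is not None else [f"env{j}" for j in range(e)]
    ids = ids if ids is not None else [f"s{i}" for i in range(n)]
    return pio.PhenotypeMatrix(
        values, np.array(ids, dtype=object), np.array(labels, dtype=object)
    )
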