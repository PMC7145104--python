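import numpy as np
import pandas as pd
import pytest

from ascpanel import MISSING, GenotypeDataset, PopulationPartition


def make_dataset(genotypes, chromosomes=None, positions=None, populations=None,
                 allele_a="A", allele_b="C"):
    """Build a valid dataset from a genotype matrix with minimal boilerplate."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_s, n_l = g.shape
    if chromosomes is None:
        chromosomes = ["1"] * n_l
    if positions is None:
        positions = list(range(1000, 1000 + 1000 * n_l, 1000))
    if populations is None:
        populations = ["POP"] * n_s
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j}" for j in range(n_l)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_a": [allele_a] * n_l,
            "allele_b": [allele_b] * n_l,
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"S{i}" for i in range(n_s)], "population_id": populations}
    )
    return GenotypeDataset(genotypes=g, loci=loci, samples=samples)


def random_dataset(rng, n_samples, n_loci, missing_rate=0.1, n_pops=2):
    """Random valid dataset with genuine polymorphism and missing calls."""
    p = rng.uniform(0.1, 0.9, n_loci)
    g = rng.binomial(2, p, size=(n_samples, n_loci)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = MISSING
    pops = [f"P{i % n_pops}" for i in range(n_samples)]
    chroms = [str(1 + j % 3) for j in range(n_loci)]
    positions = [1000 * (1 + j // 3) for j in range(n_loci)]
    ds = make_dataset(g, chromosomes=chroms, positions=positions, populations=pops)
    return ds.sort_loci()


def flip_polarity(dataset, loci_to_flip=None):
    """Swap the counted allele at the given loci (g -> 2 - g, labels swapped)."""
    g = dataset.genotypes.copy()
    loci = dataset.loci.copy()
    idx = range(dataset.n_loci) if loci_to_flip is None else loci_to_flip
    for j in idx:
        col = g[:, j]
        ok = col != MISSING
        col[ok] = 2 - col[ok]
        a, b = loci.loc[j, "allele_a"], loci.loc[j, "allele_b"]
        loci.loc[j, "allele_a"], loci.loc[j, "allele_b"] = b, a
    return GenotypeDataset(genotypes=g, loci=loci, samples=dataset.samples.copy())


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_two_pop(rng):
    """20 samples x 30 loci, two populations, with missing calls."""
    ds = random_dataset(rng, 20, 30, missing_rate=0.05)
    return ds, PopulationPartition.from_dataset(ds)
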