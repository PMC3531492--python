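"""Shared fixtures: a small simulated panel reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from bonenet import netbuild, synth
from bonenet.datatypes import GenomeSpec


SMALL_GENOME = GenomeSpec(
    chromosomes=[("chr1", 60_000_000), ("chr2", 60_000_000)], snp_count=150)


@pytest.fixture(scope="session")
def small_genome():
    return SMALL_GENOME


@pytest.fixture(scope="session")
def small_genotypes(small_genome):
    return synth.simulate_genotypes(96, 8, small_genome, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_genotypes):
    return synth.make_planted_truth(
        small_genotypes, small_genome, seed=12, n_genes=400, n_modules=4,
        module_size_range=(30, 60))


@pytest.fixture(scope="session")
def small_expression(small_genotypes, small_truth):
    return synth.simulate_expression(small_genotypes, small_truth, seed=13)


@pytest.fixture(scope="session")
def small_network(small_expression):
    """Correlation, TOM and module partition for the small panel."""
    cor = netbuild.correlation_matrix(small_expression)
    soft = netbuild.pick_soft_threshold(cor)
    adj = netbuild.adjacency(cor, soft.beta)
    tom = netbuild.tom_similarity(adj)
    part = netbuild.detect_modules(small_expression, tom)
    return {"cor": cor, "soft": soft, "adj": adj, "tom": tom, "part": part}


def pearson_oracle(x, y):
    """Textbook covariance / sigma Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def random_expression(n_genes, n_strains, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n_genes, n_strains)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_strains)])
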