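"""Shared fixtures: tiny hand-checkable instances and synthetic panels."""

import numpy as np
import pytest

from coreselect import (
    Dataset,
    DistanceMatrix,
    GenotypeMatrix,
    Locus,
    SyntheticSpec,
    generate_genotypes,
)


def matrix_from_pairs(n, pairs):
    d = np.zeros((n, n))
    for (i, j), v in pairs.items():
        d[i, j] = d[j, i] = v
    return d


@pytest.fixture(scope="session")
def toy_distance():
    """4-accession matrix whose nearest-entry sums are easy by hand."""
    d = matrix_from_pairs(
        4,
        {(0, 1): 0.1, (0, 2): 0.5, (0, 3): 0.6, (1, 2): 0.4, (1, 3): 0.7, (2, 3): 0.2},
    )
    return DistanceMatrix(["a1", "a2", "a3", "a4"], d)


@pytest.fixture(scope="session")
def toy_dataset(toy_distance):
    return Dataset(distances=toy_distance)


@pytest.fixture(scope="session")
def elimination_distance():
    """4-accession matrix for hand-checked iterated elimination."""
    d = matrix_from_pairs(
        4,
        {(0, 1): 0.1, (0, 2): 0.3, (0, 3): 0.4, (1, 2): 0.6, (1, 3): 0.8, (2, 3): 0.5},
    )
    return DistanceMatrix(["b1", "b2", "b3", "b4"], d)


@pytest.fixture(scope="session")
def biallelic_toy():
    """3 accessions x 2 biallelic loci, second locus monomorphic."""
    freq = np.array(
        [
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 1.0, 0.0],
            [0.5, 0.5, 1.0, 0.0],
        ]
    )
    loci = [Locus("l1", ("A", "a")), Locus("l2", ("B", "b"))]
    return GenotypeMatrix(["x", "y", "z"], loci, freq)


@pytest.fixture(scope="session")
def snp_panel():
    """Mid-sized synthetic SNP panel shared across modules."""
    return generate_genotypes(SyntheticSpec(n=60, n_loci=40, seed=101))


@pytest.fixture(scope="session")
def snp_dataset(snp_panel):
    return Dataset(genotypes=snp_panel)


@pytest.fixture(scope="session")
def ssr_panel():
    return generate_genotypes(
        SyntheticSpec(n=40, marker_model="multiallelic-SSR", n_loci=12, seed=7)
    )
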