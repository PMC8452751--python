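"""Shared fixtures: small hand-built matrices and seeded collections."""

import numpy as np
import pytest

from markerqc import (
    CollectionConfig,
    GenotypeMatrix,
    LabeledDataset,
    labeled_collection,
    scale_config,
)
from markerqc.synthetic_data import small_panel_config


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """4 samples x 3 loci with one het and one missing call."""
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        locus_ids=["L1", "L2", "L3"],
        dosage=np.array(
            [
                [0, 0, 2],
                [0, 1, 2],
                [2, 2, -1],
                [2, 1, 0],
            ],
            dtype=np.int8,
        ),
        alleles=[("A", "G"), ("C", "T"), ("G", "T")],
    )


@pytest.fixture(scope="session")
def default_collection():
    """The full-size default collection (625 x 158), seed 0."""
    return labeled_collection(CollectionConfig(seed=0))


@pytest.fixture(scope="session")
def default_ds(default_collection) -> LabeledDataset:
    return default_collection[0]


@pytest.fixture(scope="session")
def default_truth(default_collection):
    return default_collection[1]


@pytest.fixture(scope="session")
def scaled_collection():
    """A fifth-size collection for faster end-to-end tests."""
    return labeled_collection(scale_config(CollectionConfig(seed=1), 0.2))


@pytest.fixture(scope="session")
def clean_panel_collection():
    """Small 80-accession panel without missingness (noise-free trees)."""
    return labeled_collection(
        small_panel_config(seed=2, missing_rate_max=0.0, high_missing_rate=0.0)
    )


def random_matrix(
    rng: np.random.Generator,
    n: int,
    m: int,
    missing_frac: float = 0.1,
    het_frac: float = 0.1,
) -> GenotypeMatrix:
    """A random matrix with holes, shared by several oracle tests."""
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    het = rng.random((n, m)) < het_frac
    dosage[het] = 1
    holes = rng.random((n, m)) < missing_frac
    dosage[holes] = -1
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        locus_ids=[f"L{j}" for j in range(m)],
        dosage=dosage,
    )
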