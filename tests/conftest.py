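import numpy as np
import pytest

from nbgwas import (GenotypeTable, SpatialMap, build_neighbor_index,
                    generate_genotypes, lattice_thresholds, place_on_grid)


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeTable:
    """60 individuals x 80 markers, mild structure, fixed seed."""
    return generate_genotypes(n=60, q=80, n_subpop=2, fst=0.1, seed=11)


@pytest.fixture(scope="session")
def checkered_map() -> SpatialMap:
    """10 x 12 checkered grid fully occupied by 60 individuals."""
    return place_on_grid(60, rows=10, cols=12, checkered=True, seed=12)


@pytest.fixture(scope="session")
def neighbor_index(checkered_map):
    return build_neighbor_index(checkered_map,
                                lattice_thresholds(checkered_map, 3))


def make_genotype_table(values: np.ndarray) -> GenotypeTable:
    """Wrap a raw ±1 matrix in a GenotypeTable with synthetic metadata."""
    n, q = values.shape
    return GenotypeTable(
        values=values,
        marker_ids=np.array([f"1:{k + 1}" for k in range(q)], dtype=object),
        chrom=np.full(q, "1", dtype=object),
        pos=np.arange(1, q + 1),
        individual_ids=np.array([f"i{j}" for j in range(n)], dtype=object),
    )
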