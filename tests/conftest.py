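import numpy as np
import pandas as pd
import pytest

from lobeqtl.core import GeneticMap, Population
from lobeqtl.simulate import CrossDesign, simulate_cross, study_marker_panel


@pytest.fixture(scope="session")
def panel():
    return study_marker_panel()


@pytest.fixture(scope="session")
def toy_map():
    """Three autosomal markers, 20 cM apart."""
    return GeneticMap(names=["m1", "m2", "m3"], chrom=["2", "2", "2"], pos=[0.0, 20.0, 40.0])


@pytest.fixture(scope="session")
def f2_toy(toy_map):
    """A small F2 on the toy map, fully genotyped."""
    return simulate_cross(CrossDesign(t=2, n_phenotyped=300, census=200), toy_map, seed=42)


def population_from_genotypes(gmap, genotypes, phenotypes=None):
    """Assemble a Population directly from a genotype matrix (test helper)."""
    n = len(genotypes)
    return Population(
        ids=np.array([f"ind{i:03d}" for i in range(n)]),
        genotypes=np.asarray(genotypes, dtype=np.int8),
        gmap=gmap,
        phenotypes=pd.DataFrame(index=range(n)) if phenotypes is None else phenotypes,
    )
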