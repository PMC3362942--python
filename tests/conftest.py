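import numpy as np
import pandas as pd
import pytest

from agemap import GeneticMap, StudyDesign, simulate_genotypes


@pytest.fixture(scope="session")
def default_map() -> GeneticMap:
    return GeneticMap.evenly_spaced()


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Two chromosomes, four markers each, 30 cM."""
    rows = []
    for chrom in ("c1", "c2"):
        for i, pos in enumerate(np.linspace(0, 30, 4), start=1):
            rows.append((f"{chrom}m{i}", chrom, float(pos)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


@pytest.fixture(scope="session")
def design36() -> StudyDesign:
    return StudyDesign(seed=7)


@pytest.fixture(scope="session")
def panel36(design36, default_map):
    return simulate_genotypes(design36, default_map)
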