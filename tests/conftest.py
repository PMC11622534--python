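import warnings

import numpy as np
import pytest

from breedscan import sim_panel as sp
from breedscan.panel_io import GenotypeMatrix


@pytest.fixture(scope="session")
def default_panel():
    """One default breeding-simulation panel, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sp.simulate_panel(sp.default_breeding_plan(7), sp.default_genome_map(),
                                 sp.default_effect_model(), seed=7)


@pytest.fixture()
def toy_matrix():
    """5 lines x 6 variants with one missing call and known dosages."""
    chrom = np.array([1, 1, 2, 2, 3, 3])
    pos = np.array([100, 200, 150, 900, 40, 70])
    calls = np.array([
        [0, 1, 0, 1, 0, 1],
        [0, 1, 1, 0, 0, 1],
        [1, 0, 0, 1, 0, 0],
        [1, 0, 1, np.nan, 0, 0],
        [0, 1, 0, 1, 0, 1],
    ], dtype=float)
    return GenotypeMatrix([f"L{i}" for i in range(5)], chrom, pos,
                          np.array(list("ACGTAC"), dtype=object),
                          np.array(list("TGCAGT"), dtype=object), calls)


def random_genotypes(rng, n_lines, n_variants, freq_range=(0.1, 0.9), chrom=1):
    """Helper: iid random inbred genotype matrix on one chromosome."""
    freqs = rng.uniform(*freq_range, n_variants)
    calls = (rng.random((n_lines, n_variants)) < freqs).astype(float)
    pos = np.arange(1, n_variants + 1) * 1000
    return GenotypeMatrix([f"L{i}" for i in range(n_lines)],
                          np.full(n_variants, chrom), pos,
                          np.full(n_variants, "A", dtype=object),
                          np.full(n_variants, "T", dtype=object), calls)
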