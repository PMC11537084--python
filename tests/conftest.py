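import numpy as np
import pytest

from markerbench import synthgen
from markerbench.extract import extract_regions


@pytest.fixture(scope="session")
def small_reference_set():
    """2 genera x 3 species x 2 genomes, 1-2 operon copies each."""
    cfg = synthgen.TaxonomyConfig(
        n_genera=2, species_per_genus=3, genomes_per_species=2,
        copies_per_genome=(1, 2), seed=7)
    return synthgen.generate_reference_set(cfg)


@pytest.fixture(scope="session")
def markers_by_region(small_reference_set):
    out = {}
    for region in ("operon", "16S", "23S", "5S", "V3V4"):
        records, _ = extract_regions(small_reference_set, region)
        out[region] = records
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
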