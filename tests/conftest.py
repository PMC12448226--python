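import numpy as np
import pandas as pd
import pytest

from clinekit import synthetic_data as sd
from clinekit.core_io import GenotypeMatrix


def make_gm(counts, chrom="chr1", spacing=10_000, ploidy=None, start=10_000):
    """GenotypeMatrix from a plain (samples x loci) count array."""
    counts = np.asarray(counts, dtype=np.int16)
    n, m = counts.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(m),
            "ref": "A",
            "alt": "C",
        }
    )
    if ploidy is None:
        ploidy = np.full((n, m), 2, dtype=np.int8)
    return GenotypeMatrix([f"s{i}" for i in range(n)], loci, counts, ploidy)


@pytest.fixture(scope="session")
def small_dataset():
    """Parental panels + transect used by several module tests."""
    cfg = sd.SyntheticConfig(
        seed=3, n_parental_each=12, n_transect=60, l_diag=200, l_background=100
    )
    gm, table = sd.make_dataset(cfg)
    return cfg, gm, table


@pytest.fixture(scope="session")
def panel_ids(small_dataset):
    _, _, table = small_dataset
    a = table[table.population_label == "allopatric-P0"].sample_id.tolist()
    b = table[table.population_label == "allopatric-P1"].sample_id.tolist()
    return a, b
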