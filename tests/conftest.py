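import numpy as np
import pandas as pd
import pytest

from pepatlas import synthetic as syn
from pepatlas.pipeline import identify_peptides


@pytest.fixture(scope="session")
def default_atlas():
    """Full-size synthetic atlas under the standard study conditions."""
    return syn.generate_atlas(syn.default_config(seed=7))


@pytest.fixture(scope="session")
def identified_records(default_atlas):
    return identify_peptides(
        default_atlas.models, default_atlas.peptides, default_atlas.abundance)


@pytest.fixture(scope="session")
def small_atlas():
    """A quick-to-generate atlas for io/CLI and landscape tests."""
    cfg = syn.SyntheticConfig(
        seed=11, n_chromosomes=3, chrom_length_bp=800_000, n_genes=60,
        n_peptides=300,
    )
    return syn.generate_atlas(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_positions(atlas) -> pd.DataFrame:
    """Peptide genomic starts straight from the generator's truth."""
    idx = atlas.peptides.index
    return pd.DataFrame(
        {
            "chrom": [atlas.truth.genomic_start[p][0] for p in idx],
            "start": [atlas.truth.genomic_start[p][1] for p in idx],
        },
        index=idx,
    )
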