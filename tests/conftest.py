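import numpy as np
import pandas as pd
import pytest

from epicoord import enrichment as er
from epicoord.synthetic_data import SimConfig, simulate_genome, simulate_tracks


SMALL = dict(n_chroms=2, chrom_length=2_000_000, n_genes=40, n_enhancers=30,
             n_terms=12, term_size=10, n_ppi_modules=2, ppi_module_size=8,
             n_ppi_background_edges=80)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_genome(small_config):
    genes, chrom_sizes = simulate_genome(small_config)
    return genes, chrom_sizes


@pytest.fixture(scope="session")
def small_study(small_config, small_genome):
    """A small simulated study shared by unit tests (read-only)."""
    genes, chrom_sizes = small_genome
    tracks, truth = simulate_tracks(genes, small_config)
    return dict(config=small_config, genes=genes, chrom_sizes=chrom_sizes,
                tracks=tracks, truth=truth)


def make_track(values_by_chrom, mark="M", condition="epithelial", kind="RE"):
    data = {c: np.asarray(v) for c, v in values_by_chrom.items()}
    return er.BinnedTrack(data=data, mark=mark, condition=condition, kind=kind)


@pytest.fixture
def simple_genes():
    return pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "strand": ["+", "-", "+"],
        "txStart": [10_000, 50_000, 20_000],
        "txEnd": [14_000, 56_000, 23_000],
    })
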