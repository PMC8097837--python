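import pandas as pd
import pytest

from genecag import GeneCatalog
from genecag.manifest import Manifest
from genecag.synthetic import ExperimentConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic experiment shared by read-level tests."""
    config = ExperimentConfig(
        n_genes=120,
        n_cags=15,
        n_specimens_per_group=(12, 12),
        n_associated=6,
        reads_per_specimen=2000,
    )
    return generate_experiment(config, seed=42)


@pytest.fixture(scope="session")
def small_manifest(small_experiment):
    exp = small_experiment
    return Manifest(rows=exp.manifest, covariates=exp.covariates)


@pytest.fixture
def tiny_catalog():
    return GeneCatalog(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "length_aa": [200, 100, 150],
                "taxon": ["tax1", "tax1", "tax2"],
                "function": ["fn1", None, "fn2"],
            }
        )
    )


def make_alignment(specimen, read_id, gene_id, score=50.0, start=1, end=50, bases=150):
    return {
        "specimen": specimen,
        "read_id": read_id,
        "gene_id": gene_id,
        "score": score,
        "gene_start": start,
        "gene_end": end,
        "aligned_bases": bases,
    }


@pytest.fixture
def alignment_row():
    return make_alignment
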