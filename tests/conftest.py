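import numpy as np
import pandas as pd
import pytest

from tcellkit.simulate import (
    BarcodeSimSpec,
    GenomeSimSpec,
    RepertoireSimSpec,
    simulate_barcodes,
    simulate_domain_hits,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def barcode_sim():
    """Default empty+cell mixture (valley planted at log10 ~ 2.30)."""
    spec = BarcodeSimSpec(seed=1)
    return simulate_barcodes(spec)


@pytest.fixture(scope="session")
def genome_sim():
    """50 planted 3-domain genes, fully annotated."""
    spec = GenomeSimSpec(n_scaffolds=5, genes_per_scaffold=10, domains_per_gene=3,
                         annotated_fraction=1.0, seed=2)
    return simulate_domain_hits(spec)


@pytest.fixture(scope="session")
def repertoire_sim():
    """2,000 cells / 4 samples, dominant at 0.34, dropout 0.3, ambiguity 0.2."""
    spec = RepertoireSimSpec(n_cells_per_sample=500, n_samples=4, n_clonotypes=200,
                             dominant_fraction=0.34, chain_dropout_alpha_delta=0.3,
                             ambiguity_rate=0.2, seed=7)
    return simulate_repertoire(spec)


@pytest.fixture(scope="session")
def clean_repertoire_sim():
    """Same population without dropout or ambiguity."""
    spec = RepertoireSimSpec(n_cells_per_sample=250, n_samples=2, n_clonotypes=50,
                             dominant_fraction=0.34, chain_dropout_alpha_delta=0.0,
                             ambiguity_rate=0.0, seed=9)
    return simulate_repertoire(spec)


@pytest.fixture(scope="session")
def called_repertoire(repertoire_sim):
    """Clonotype pipeline output on the noisy repertoire, joined to truth."""
    from tcellkit.clonotype import assign_clonotypes

    records, seqs, truth = repertoire_sim
    result = assign_clonotypes(records, seqs)
    table = result.table.merge(truth[["cell_barcode", "sample_id"]], on="cell_barcode")
    return result, table, truth


def shared_pool_table(rng: np.random.Generator, n_clonotypes: int,
                      n_samples: int = 8, n_cells: int = 500,
                      n_clonotypes_b: int | None = None,
                      prefix_groups: bool = False) -> pd.DataFrame:
    """Cell-level clonotype table: samples drawing from one shared clonotype
    frequency vector (or a second vector for the last half of samples)."""
    pa = rng.dirichlet(np.ones(n_clonotypes))
    pb = None
    if n_clonotypes_b is not None:
        pb = rng.dirichlet(np.ones(n_clonotypes_b))
    rows = []
    for s in range(n_samples):
        second = pb is not None and s >= n_samples // 2
        p = pb if second else pa
        k = n_clonotypes_b if second else n_clonotypes
        tag = ("B" if second else "A") if prefix_groups or pb is not None else ""
        for d in rng.choice(k, size=n_cells, p=p):
            rows.append({"sample_id": f"S{s}", "clonotype": f"{tag}c{d}"})
    return pd.DataFrame(rows)
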