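import numpy as np
import pytest

import degas
from degas import scores as sc
from degas.simulate import (
    simulate_annotations,
    simulate_enrichment_fixture,
    simulate_latent_model,
    to_zmatrix,
)


@pytest.fixture(scope="session")
def latent_dataset():
    """Standard planted-structure dataset: N=200, M=500, s=(10,5,1), noise 0.1."""
    tables, phenotypes, truth = simulate_latent_model(seed=1)
    z = to_zmatrix(tables, phenotypes)
    zs = degas.standardize_phenotype_rows(z)
    d = degas.truncated_svd(zs, 3, seed=1)
    return {
        "tables": tables,
        "phenotypes": phenotypes,
        "truth": truth,
        "z": z,
        "zs": zs,
        "d": d,
    }


@pytest.fixture(scope="session")
def annotated_variants():
    variants, tss, chrom_sizes, counts = simulate_annotations(
        500,
        mhc_fraction=0.1,
        fail_missingness_fraction=0.04,
        fail_maf_fraction=0.04,
        fail_hwe_fraction=0.04,
        fail_ld_fraction=0.04,
        seed=7,
    )
    return {"variants": variants, "tss": tss, "chrom_sizes": chrom_sizes, "counts": counts}


@pytest.fixture(scope="session")
def enrichment_fixture():
    """Planted-enrichment dataset with the fitted decomposition and scores."""
    fx = simulate_enrichment_fixture(seed=0)
    z = to_zmatrix(fx["tables"], fx["phenotypes"])
    zs = degas.standardize_phenotype_rows(z)
    d = degas.truncated_svd(zs, 2, seed=0)
    fx["d"] = d
    fx["variant_contribution"] = sc.variant_contribution(d)
    fx["annotations"] = {v.variant_id: v for v in fx["variants"]}
    return fx


@pytest.fixture
def rng():
    return np.random.default_rng(0)
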