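import numpy as np
import pytest

from suspop.simgen import MISSING, GenotypeMatrix


def toy_matrix(
    alleles,
    populations,
    positions=None,
    chrom="1",
    site_class="intergenic",
    cpg=None,
    ancestral_known=True,
):
    """Small hand-built GenotypeMatrix; ``alleles`` is (n_haps, n_sites)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_haps, n_sites = alleles.shape
    assert n_haps == 2 * len(populations)
    if positions is None:
        positions = np.arange(n_sites, dtype=np.int64) * 10
    if isinstance(site_class, str):
        site_class = np.full(n_sites, site_class, dtype="U10")
    cpg = np.zeros(n_sites, dtype=bool) if cpg is None else np.asarray(cpg, bool)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(len(populations))],
        populations=list(populations),
        chrom=np.full(n_sites, chrom, dtype="U8"),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        ancestral_known=np.full(n_sites, ancestral_known, dtype=bool),
        site_class=site_class,
        cpg_flag=cpg,
    )


@pytest.fixture(scope="session")
def quartet_fixture():
    """One no-gene-flow quartet simulation shared across tests."""
    from suspop.simgen import make_fixture

    return make_fixture("no_geneflow_quartet", seed=7, n_loci=120)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
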