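import pytest

from ighgkit import reference
from ighgkit.genotype_io import GenotypeMatrix, as_call


@pytest.fixture(scope="session")
def models():
    return reference.load_gene_models()


@pytest.fixture(scope="session")
def catalog():
    return reference.load_catalog()


@pytest.fixture(scope="session")
def aliases():
    return reference.load_novel_aliases()


@pytest.fixture(scope="session")
def panel(models):
    """The study's 87-SNP panel, classified against the gene models."""
    return reference.study_snp_defs(models)


def make_matrix(snps, genotypes, population="POP"):
    """Toy GenotypeMatrix from per-sample call strings.

    ``genotypes``: list of per-sample lists, one entry per SNP, each either
    'A/G'-style or None.
    """
    samples = [f"s{i+1}" for i in range(len(genotypes))]
    calls = {snp.snp_id: {} for snp in snps}
    for sample, row in zip(samples, genotypes):
        for snp, g in zip(snps, row):
            if g is None:
                calls[snp.snp_id][sample] = None
            else:
                a, b = g.split("/")
                calls[snp.snp_id][sample] = as_call(a, b)
    pops = {s: population for s in samples} if isinstance(population, str) else dict(
        zip(samples, population)
    )
    return GenotypeMatrix(samples=samples, populations=pops, snps=list(snps),
                          calls=calls)


@pytest.fixture()
def toy_snps(models, panel):
    """Two linked IGHG1 sites: Eu 214 (K/R) and Eu 356 (D/E)."""
    by_id = {s.snp_id: s for s in panel}
    return [by_id["G1_CH1_290"], by_id["G1_CH3_47"]]
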