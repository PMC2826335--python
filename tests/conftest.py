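import numpy as np
import pytest

from ssrwild import (
    Accession,
    Allele,
    AlleleMatrix,
    Marker,
    MarkerPanel,
    SimulationConfig,
    Taxonomy,
    simulate,
)


@pytest.fixture
def tiny_taxonomy() -> Taxonomy:
    """Seven accessions over three sections, with cultivated tetraploids."""
    return Taxonomy(
        [
            Accession("AH1", "A. hypogaea", "Arachis", "AB", 40),
            Accession("AH2", "A. hypogaea", "Arachis", "AB", 40),
            Accession("DUR1", "A. duranensis", "Arachis", "A", 20),
            Accession("IPA1", "A. ipaensis", "Arachis", "B", 20),
            Accession("PIN1", "A. pintoi", "Caulorrhizae", "unassigned", 20),
            Accession("PIN2", "A. pintoi", "Caulorrhizae", "unassigned", 20),
            Accession("PUS1", "A. pusilla", "Heteranthae", "unassigned", 20),
        ]
    )


@pytest.fixture
def tiny_panel() -> MarkerPanel:
    return MarkerPanel(
        [
            Marker("M1", "genomic", (100, 500)),
            Marker("M2", "genomic", (100, 500)),
            Marker("C1", "genic", (100, 900)),
        ]
    )


def build_matrix(genotypes: dict[str, dict[str, set[int]]],
                 accessions: list[str]) -> AlleleMatrix:
    """Assemble an AlleleMatrix from {accession: {marker: {sizes}}}."""
    alleles = sorted(
        {
            Allele(m, s)
            for calls in genotypes.values()
            for m, sizes in calls.items()
            for s in sizes
        }
    )
    cells = np.zeros((len(alleles), len(accessions)), dtype=bool)
    for j, acc in enumerate(accessions):
        for m, sizes in genotypes.get(acc, {}).items():
            for s in sizes:
                cells[alleles.index(Allele(m, s)), j] = True
    return AlleleMatrix(alleles, accessions, cells)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter simulated dataset, shared across tests."""
    cfg = SimulationConfig(seed=1)
    taxonomy, panel, mat, amp, truth = simulate(cfg)
    return cfg, taxonomy, panel, mat, amp, truth
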