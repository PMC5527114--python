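import numpy as np
import pytest

from fsspipe import CohortSpec, GenotypeMatrix, GroupedGenotypeCounts, table2_fixture
from fsspipe.genotypes import CASE, CONTROL
from fsspipe.synthetic import LdBlockSpec, SnpSimSpec

#: Cluster sizes of the synthetic 34-SNP panel: 13 LD clusters.
CLUSTER_SIZES = (4, 4, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2)


def clustered_panel_spec(seed: int = 1, n_cases: int = 2000, n_controls: int = 2000,
                         or_: float = 1.6) -> CohortSpec:
    """34-SNP cohort in 13 perfect-coupling LD clusters, one per chromosome,
    each cluster carrying one causal risk allele."""
    specs, blocks = [], []
    idx = 0
    for c, size in enumerate(CLUSTER_SIZES):
        f = 0.2 + 0.02 * c
        indices = tuple(range(idx, idx + size))
        for k in range(size):
            specs.append(SnpSimSpec(rsid=f"rs_c{c}_{k}", control_freq=f, or_=1.0,
                                    chromosome=str(c + 1), position=1000 * (k + 1)))
        hap = [0.0] * 2**size
        hap[0] = 1.0 - f        # all-major haplotype
        hap[-1] = f             # all-minor (risk) haplotype: perfect coupling
        blocks.append(LdBlockSpec(indices=indices, hap_freqs=tuple(hap), or_=or_))
        idx += size
    return CohortSpec(n_cases=n_cases, n_controls=n_controls, snp_specs=tuple(specs),
                      ld_blocks=tuple(blocks), seed=seed)


@pytest.fixture(scope="session")
def fx():
    """Published 13-SNP count tables and quartile table."""
    return table2_fixture()


def expand_counts(counts: GroupedGenotypeCounts) -> GenotypeMatrix:
    """Individual-level matrix whose per-SNP tallies equal ``counts``.

    Dosage categories are expanded in (major-hom, het, minor-hom) order.
    """
    dosages, phenos = [], []
    for tri, label in ((counts.case_counts, CASE), (counts.control_counts, CONTROL)):
        for dose, n in enumerate(tri):
            dosages.extend([float(dose)] * n)
            phenos.extend([label] * n)
    n = len(dosages)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        phenotype=np.array(phenos, dtype=object),
        snps=[counts.snp],
        dosage=np.array(dosages)[:, None],
    )
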