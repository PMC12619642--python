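import numpy as np
import pytest

import airrchimera as ac
from airrchimera.chmm_core import HMMSpec


@pytest.fixture(scope="session")
def tiny_msa():
    """Two alleles, six columns, one gap in the first allele."""
    return ac.ReferenceMSA(
        [
            ac.GermlineAllele("X*01", "ACGT-A"),
            ac.GermlineAllele("Y*01", "ACGTTA"),
        ]
    )


@pytest.fixture(scope="session")
def small_db():
    """A synthetic germline database with multiple alleles per gene."""
    return ac.synthetic_germline_database(10, length=120, seed=3)


@pytest.fixture(scope="session")
def small_genotype(small_db):
    return ac.sample_synthetic_genotype(small_db, 1)


def random_hmm_instance(rng, *, max_G=5, max_K=3, max_L=50):
    """A random small model + query for oracle-equivalence checks."""
    G = int(rng.integers(2, max_G + 1))
    K = int(rng.integers(1, max_K + 1))
    L = int(rng.integers(5, max_L + 1))
    alphabet = np.array(list("ACGT-N"))
    probs_ref = np.array([0.22, 0.22, 0.22, 0.22, 0.08, 0.04])
    alleles = []
    for g in range(G):
        seq = "".join(rng.choice(alphabet, size=L, p=probs_ref))
        alleles.append(ac.GermlineAllele(f"R{g + 1}*01", seq))
    msa = ac.ReferenceMSA(alleles)
    rates = np.sort(rng.uniform(0.0, 0.3, size=K))
    psi = float(rng.uniform(1e-4, 0.05))
    mu = float(rng.uniform(1e-4, 0.05))
    spec = HMMSpec(msa=msa, rates=rates, psi=psi, mu=mu)
    probs_q = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
    query = "".join(rng.choice(alphabet, size=L, p=probs_q))
    return query, spec
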