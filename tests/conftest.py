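import numpy as np
import pytest
from hypothesis import settings

from halfsib import GenotypeMatrix, Pedigree, SnpInfo

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def half_sib_pedigree():
    """One sire, two daughters out of unrelated dams."""
    return Pedigree.from_tuples(
        [
            ("S1", None, None),
            ("M1", None, None),
            ("M2", None, None),
            ("D1", "S1", "M1"),
            ("D2", "S1", "M2"),
        ]
    )


def make_genotypes(calls, positions=None, ids=None, snp_ids=None, alleles=None):
    """GenotypeMatrix from a plain 2-D code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    ids = ids or [f"I{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    positions = positions or [100 * (j + 1) for j in range(m)]
    alleles = alleles or [("A", "B")] * m
    snps = [
        SnpInfo(snp_ids[j], "1", positions[j], alleles[j][0], alleles[j][1])
        for j in range(m)
    ]
    return GenotypeMatrix(ids, snps, calls)


def genotypes_from_haplotypes(hap_strings, freqs, n, rng, snp_ids=None):
    """n unrelated diploids with gametes drawn iid from given haplotypes.

    ``hap_strings`` are binary strings ('1' = counted allele).
    """
    haps = np.array([[int(c) for c in h] for h in hap_strings], dtype=np.int8)
    picks = rng.choice(len(haps), size=(n, 2), p=np.asarray(freqs, float))
    calls = haps[picks[:, 0]] + haps[picks[:, 1]]
    return make_genotypes(calls, snp_ids=snp_ids), picks


def random_pedigree_triples(n, rng, n_founders=None):
    n_founders = n_founders or max(2, n // 3)
    triples = [(f"I{i}", None, None) for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        triples.append((f"I{i}", f"I{s}", f"I{d}"))
    return triples
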