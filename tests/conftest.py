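import numpy as np
import pandas as pd
import pytest

from ghostdex.genodata import SITE_COLUMNS, SiteMatrix


def make_matrix(calls, chroms=None, positions=None, alleles=None,
                ancestral=None, cpg=None, samples=None, polarized=True):
    """Build a SiteMatrix directly from a call array for hand-built tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, k = calls.shape
    chroms = chroms if chroms is not None else ["1"] * n
    positions = positions if positions is not None else list(range(1, n + 1))
    if alleles is None:
        alleles = [("A", "C")] * n
    anc = ancestral if ancestral is not None else [a for a, _ in alleles]
    cpg = cpg if cpg is not None else [False] * n
    samples = samples if samples is not None else [f"s{i}" for i in range(k)]
    sites = pd.DataFrame({
        "chrom": [str(c) for c in chroms],
        "pos": positions,
        "allele_a": [a for a, _ in alleles],
        "allele_b": [b for _, b in alleles],
        "ancestral": anc,
        "is_cpg": cpg,
    })[SITE_COLUMNS]
    return SiteMatrix(sites=sites, samples=samples, calls=calls,
                      polarized=polarized)


@pytest.fixture
def random_matrix():
    """Factory: random polarized matrix with missingness, plus its rng."""

    def _make(n_sites=200, n_samples=8, missing=0.15, seed=0,
              n_chroms=2, chrom_len=1000, p_derived=0.5):
        rng = np.random.default_rng(seed)
        calls = (rng.random((n_sites, n_samples)) < p_derived).astype(np.int8)
        calls[rng.random((n_sites, n_samples)) < missing] = -1
        chroms = rng.integers(1, n_chroms + 1, size=n_sites)
        pos = rng.integers(1, chrom_len + 1, size=n_sites)
        order = np.lexsort((pos, chroms))
        return make_matrix(calls[order],
                           chroms=[str(c) for c in chroms[order]],
                           positions=pos[order].tolist())

    return _make
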