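import numpy as np
import pytest

import lightchrom as lc


@pytest.fixture(scope="session")
def small_genome():
    """50 kb single-contig random genome, GC 0.5."""
    return lc.make_genome(n_contigs=1, contig_length=50_000, gc_fraction=0.5, seed=0)


@pytest.fixture(scope="session")
def small_genes(small_genome):
    return lc.make_annotation(
        small_genome, n_genes=20, min_gene_length=800, max_gene_length=1500,
        min_intergenic=300, seed=1,
    )


@pytest.fixture(scope="session")
def flat_fit():
    """Dispersion mapping with sigma^2(mu) = mu (Poisson limit)."""

    class PoissonFit:
        def __call__(self, mu):
            return np.asarray(mu, dtype=float) if np.ndim(mu) else float(mu)

        def dispersion(self, mu):
            return 0.0

    return PoissonFit()


def make_const_var_fit(var):
    """Dispersion mapping with constant sigma^2 regardless of mu."""

    class ConstFit:
        def __call__(self, mu):
            return var

        def dispersion(self, mu):
            return max(0.0, (var - mu) / mu**2) if mu > 0 else 0.0

    return ConstFit()
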