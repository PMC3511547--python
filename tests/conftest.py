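import numpy as np
import pytest

from imputeval.core_io import GenotypeMatrix, PosteriorMatrix, VariantRecord

NONAMBIG = (("A", "G"), ("T", "C"), ("C", "A"), ("G", "T"))


def make_variants(n, chrom="22", start=100):
    out = []
    for i in range(n):
        ref, alt = NONAMBIG[i % len(NONAMBIG)]
        out.append(VariantRecord(chrom, start + i, f"rs{i}", ref, alt))
    return out


def make_genotypes(calls, samples=None, chrom="22"):
    calls = np.asarray(calls, dtype=np.int8)
    if samples is None:
        samples = [f"S{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(make_variants(calls.shape[0], chrom), samples, calls)


def make_posterior(probs, samples=None, chrom="22"):
    probs = np.asarray(probs, dtype=np.float64)
    if samples is None:
        samples = [f"S{j}" for j in range(probs.shape[1])]
    return PosteriorMatrix(make_variants(probs.shape[0], chrom), samples, probs)


def hwe_genotypes(rng, p, size):
    """Direct HWE draw: Binomial(2, p)."""
    return rng.binomial(2, p, size=size).astype(np.int8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
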