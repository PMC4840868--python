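import io

import pytest

import shadowspline as ss


@pytest.fixture(scope="session")
def linear_pairs():
    """Noisy linear read-shadow pairs with slope 0.25 (true rate 0.2)."""
    return ss.generate_linear_pairs(0.25, intercept=0.0, noise=5.0, m=1000, seed=101)


@pytest.fixture(scope="session")
def sample_10k():
    """Small synthetic FASTQ sample: 10k reads over 50 sources at per-base
    error rate 0.002, with full truth."""
    spec = ss.FixtureSpec(
        reference_length=2000,
        n_sources=50,
        abundance=0.7,
        read_length=36,
        error_rate=0.002,
        total_reads=10_000,
        seed=11,
    )
    fastq, truth = ss.generate_sample(spec)
    return spec, fastq, truth


@pytest.fixture(scope="session")
def sample_100k():
    """Full-scale synthetic sample: 100k reads, 1200 sources, per-base
    error 0.001 — the known-truth end-to-end pipeline input."""
    spec = ss.FixtureSpec(
        reference_length=3000,
        n_sources=1200,
        abundance=0.5,
        read_length=36,
        error_rate=0.001,
        total_reads=100_000,
        seed=42,
    )
    fastq, truth = ss.generate_sample(spec)
    table = ss.count_reads(io.StringIO(fastq))
    return spec, truth, table
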