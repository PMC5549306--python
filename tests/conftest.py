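import numpy as np
import pytest

from cnvfam import SnpLocus, SyntheticCohortSpec, generate_cohort


def tiny_spec(**overrides) -> SyntheticCohortSpec:
    """A scaled-down cohort for fast unit tests: 30 families on a 4-chromosome
    miniature array with sparse rare CNVs."""
    defaults = dict(
        n_families=30,
        n_chromosomes=4,
        window_span_bp=2_000_000,
        rare_del_rate=3.0,
        rare_dup_rate=1.5,
        n_background_common=4,
        seed=101,
    )
    defaults.update(overrides)
    return SyntheticCohortSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_spec())


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (~444 siblings / 192 families)."""
    return generate_cohort(SyntheticCohortSpec(seed=7))


def grid_map(n_probes: int, chrom: str = "chr1", start: int = 1000, spacing: int = 1000):
    """A regular probe map for hand-built QC examples."""
    return [
        SnpLocus(snp_id=f"p{i}", chrom=chrom, position_bp=start + i * spacing)
        for i in range(n_probes)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
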