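import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cnvburden import (
    CnvCall,
    GenomicInterval,
    SampleRecord,
    SimulationConfig,
    simulate_cohort,
)


def make_call(sample, chrom, start, end, cnv_type="deletion", callers=("c1",), source_id=None):
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        cnv_type=cnv_type,
        callers=frozenset(callers),
        source_id=source_id,
    )


def make_sample(sid, phenotype="case", **kw):
    defaults = dict(
        sex="female", age=50.0, bmi=28.0, cholesterol=200.0,
        triglycerides=150.0, mds1=0.0, mds2=0.0, mds3=0.0,
    )
    defaults.update(kw)
    return SampleRecord(sample_id=sid, phenotype=phenotype, **defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy cohort reused by read-only tests."""
    config = SimulationConfig(
        n_cases=60, n_controls=40, n_genes=80, n_gene_sets=8, seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no caller dropout, no boundary jitter."""
    config = SimulationConfig(
        n_cases=50, n_controls=30, n_genes=60, n_gene_sets=6,
        caller_dropout=0.0, boundary_jitter_sd=0.0, seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
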