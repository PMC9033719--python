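import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from haplocharter.cohort import CohortConfig, generate_cohort
from haplocharter.variants import GenotypeMatrix, VariantSite

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(records, samples=None, phased=True, region=None):
    """Build a GenotypeMatrix from (pos, ref, alts, genotype-rows[, qual]).

    Genotype rows are lists of (a, b) allele-index pairs; -1 is missing.
    """
    n = len(records[0][3])
    samples = samples or [f"S{i + 1}" for i in range(n)]
    sites, rows = [], []
    for rec in records:
        pos, ref, alts, gts = rec[:4]
        qual = rec[4] if len(rec) > 4 else 60.0
        sites.append(
            VariantSite(chrom="Gm20", pos=pos, ref=ref,
                        alts=tuple(alts), qual=qual)
        )
        rows.append(gts)
    gt = np.array(rows, dtype=np.int16)
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=gt,
                          phased=phased, region=region)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for pipeline-level tests."""
    cfg = CohortConfig(
        n_wild=40, n_landrace=120, n_old_cultivar=10, n_modern_cultivar=30,
        background_snp_count=40, seed=11,
    )
    return generate_cohort(cfg)
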