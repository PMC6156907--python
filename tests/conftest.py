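import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import haplasso as hp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_snp_list():
    """The 2-SNP block with all four haplotypes: 11, 10, 01, 00."""
    return hp.HaplotypeList.from_strings(["11", "10", "01", "00"])


@pytest.fixture
def biallelic_list():
    """A single-SNP block (K=1): haplotypes '0' (baseline) and '1'."""
    return hp.HaplotypeList.from_strings(["0", "1"])


@pytest.fixture
def small_pool():
    """3-SNP pool with 4 haplotypes; the rare one (f=0.1) is the risk target."""
    hl = hp.HaplotypeList.from_strings(["000", "010", "101", "111"])
    fv = hp.FrequencyVector(np.array([0.5, 0.25, 0.15, 0.1]))
    return hl, fv


@pytest.fixture
def k1_params():
    """K=1 parameters with per-copy odds 3 (hom odds 9), balanced pool."""
    return hp.ParameterVector(
        regression=hp.RegressionParams(alpha=0.0, beta=np.array([np.log(3.0)])),
        freqs=hp.FrequencyVector(np.array([0.5, 0.5])),
    )


def make_subjects(dosage_counts, L=1, pedigree_prefix="s"):
    """Build SubjectRecords from {(dosage, phenotype): count} for 1-SNP data."""
    out = []
    i = 0
    for (g, y), n in dosage_counts.items():
        for _ in range(n):
            out.append(hp.SubjectRecord(
                genotype=np.full(L, g, dtype=np.int8), phenotype=y,
                pedigree_id=f"{pedigree_prefix}{i}", subject_id=f"{pedigree_prefix}{i}",
            ))
            i += 1
    return out


@pytest.fixture
def k1_dataset():
    """Fixed 30-subject single-SNP dataset (phases always forced at L=1)."""
    return make_subjects({
        (2, 1): 5, (1, 1): 4, (0, 1): 1,
        (2, 0): 2, (1, 0): 6, (0, 0): 12,
    })
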