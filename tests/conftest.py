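import numpy as np
import pytest

from chipcall.classifier import (FilterThresholds, SampleContext, VariantCall,
                                 default_driver_rules)
from chipcall.simulate import SimConfig, simulate_cohort


def make_variant(sample_id="S1", gene="DNMT3A", chrom="2", pos=25457243,
                 ref="C", alt="T", variant_class="missense",
                 protein_change="p.R882H", alt_count=30, ref_count=170,
                 tlod=50.0, qsi_nt=None) -> VariantCall:
    return VariantCall(sample_id=sample_id, gene=gene, chrom=chrom, pos=pos,
                       ref=ref, alt=alt, variant_class=variant_class,
                       protein_change=protein_change, alt_count=alt_count,
                       ref_count=ref_count, tlod=tlod, qsi_nt=qsi_nt)


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """P[Bin(n, p) >= k] by direct summation (independent of scipy)."""
    import math
    if k <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    total = 0.0
    logp, logq = math.log(p), math.log(1.0 - p)
    for i in range(k, n + 1):
        total += math.exp(math.lgamma(n + 1) - math.lgamma(i + 1)
                          - math.lgamma(n - i + 1) + i * logp
                          + (n - i) * logq)
    return min(total, 1.0)


@pytest.fixture(scope="session")
def thresholds():
    return FilterThresholds()


@pytest.fixture(scope="session")
def rules():
    return default_driver_rules()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort, shared across tests."""
    return simulate_cohort(SimConfig(seed=20240901))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast pipeline-level tests."""
    return simulate_cohort(SimConfig(n_patients=180, seed=7))


def ctx(sample_id="S1", contamination=0.01, tumor_fraction=None,
        mean_depth=978.0) -> SampleContext:
    return SampleContext(sample_id=sample_id, contamination=contamination,
                         tumor_fraction=tumor_fraction, mean_depth=mean_depth)
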