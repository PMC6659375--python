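import numpy as np
import pytest

from epimr.records import AssociationRecord, VariantKey
from epimr.simulate import SimulationConfig, simulate_region


def make_record(
    beta=0.1, se=0.02, pvalue=None, eaf=0.3, n=1000,
    vid="rs1", pos=100, ea="A", oa="G", chrom="1",
):
    """Convenience factory for one-off association records."""
    if pvalue is None:
        from scipy import stats

        pvalue = float(max(2 * stats.norm.sf(abs(beta / se)), 5e-324))
    return AssociationRecord(
        variant=VariantKey(
            id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa
        ),
        beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n,
    )


@pytest.fixture(scope="session")
def shared_region():
    """One colocalizing region reused by read-only tests."""
    return simulate_region(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
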