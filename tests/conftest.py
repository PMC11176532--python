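import numpy as np
import pytest

from mrkit.sumstats import SummaryTable, VariantAssociation


def make_assoc(vid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
               beta=0.1, se=0.02, pval=None, n=10000.0):
    """A valid association row; p derived from beta/se unless given."""
    if pval is None:
        from scipy import stats
        pval = float(max(2 * stats.norm.sf(abs(beta / se)), 1e-300))
    return VariantAssociation(vid, chrom, pos, ea, oa, eaf, beta, se,
                              pval, n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240531)


@pytest.fixture
def three_row_table():
    rows = [
        make_assoc("rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.02),
        make_assoc("rs2", "2", 2000, "C", "T", 0.4, -0.05, 0.01),
        make_assoc("rs3", "3", 3000, "G", "A", 0.2, 0.02, 0.015),
    ]
    return SummaryTable("trait", "binary", rows)
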