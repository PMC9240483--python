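import numpy as np
import pytest

from bsascan import BulkSite


def make_site(chrom="chr1", pos=1000, ref="A", alts=("G",),
              pl=(30, 0), ps=(0, 28), laa=41, saa=29, lab=12, sab=60,
              informative=True, bd_aa=None, bd_ab=None):
    """Handcrafted BulkSite with consistent base depths by default."""
    if bd_aa is None:
        bd_aa = {ref: laa, alts[0]: saa}
    if bd_ab is None:
        bd_ab = {ref: lab, alts[0]: sab}
    return BulkSite(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                    parent_L_depths=tuple(pl), parent_S_depths=tuple(ps),
                    Laa=laa, Saa=saa, Lab=lab, Sab=sab,
                    base_depths_aa=dict(bd_aa), base_depths_ab=dict(bd_ab),
                    parent_informative=informative)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def site_factory():
    return make_site
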