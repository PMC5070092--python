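import numpy as np
import pytest

from poolsex.io_formats import PooledSiteCount
from poolsex.sexsnp import SiteStats


def make_site(chrom="LG1", pos=100, ref="A", alt="G",
              p1_ref=18, p1_alt=12, p2_ref=30, p2_alt=0) -> PooledSiteCount:
    return PooledSiteCount(chrom, pos, ref, alt, p1_ref, p1_alt, p2_ref, p2_alt)


def make_stats(chrom="LG1", pos=100, sex_patterned=False, fst=None,
               x_allele=None, y_allele=None) -> SiteStats:
    s = SiteStats(site=make_site(chrom=chrom, pos=pos), evaluated=True,
                  is_sex_patterned=sex_patterned, fst=fst)
    s.x_allele, s.y_allele = x_allele, y_allele
    if sex_patterned and x_allele is None:
        s.x_allele, s.y_allele = "A", "G"
    s.p_het, s.p_hom = (0.5, 0.0) if sex_patterned else (0.3, 0.3)
    return s


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
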