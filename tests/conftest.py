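import numpy as np
import pytest

from pegkit import Locus, build_pegrna, parse_label, scan_pam_sites

# toy locus: a 20-nt protospacer, its AGG PAM, and downstream context;
# nick falls between protospacer positions 17/18, i.e. top-strand index 17
TOY_SPACER = "GACCTTAACGGATGCAAGTC"
TOY_SEQ = TOY_SPACER + "AGG" + "TTCAGGCCTA"


@pytest.fixture
def toy_locus():
    return Locus(name="toy", sequence=TOY_SEQ)


@pytest.fixture
def toy_site(toy_locus):
    sites = [s for s in scan_pam_sites(toy_locus)
             if s.strand == "+" and s.spacer_start == 0]
    assert len(sites) == 1
    return sites[0]


@pytest.fixture
def toy_edit(toy_locus, toy_site):
    return parse_label("+1 T ins", toy_site, toy_locus)


@pytest.fixture
def toy_pegrna(toy_locus, toy_edit, toy_site):
    return build_pegrna(toy_locus, toy_edit, toy_site, pbs_len=4, rt_homology_len=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
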