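import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from gcdiv.types import ChimeraMix, ObservedSectionData, SectionGeometry


@pytest.fixture
def paper_mix() -> ChimeraMix:
    """The hemopoietic-chimera mixing fraction, p = 0.21."""
    return ChimeraMix(p=0.21)


@pytest.fixture
def paper_data(paper_mix) -> ObservedSectionData:
    """Observed section classification: 14% pure-A, 6% pure-B, 80% mixed."""
    return ObservedSectionData(pct_A=14.0, pct_B=6.0, pct_Mix=80.0, mix=paper_mix)


@pytest.fixture
def paper_geom() -> SectionGeometry:
    """GC of 5000 B cells, sections of 200."""
    return SectionGeometry(M=5000, m=200)


@pytest.fixture
def small_geom() -> SectionGeometry:
    return SectionGeometry(M=10, m=4)
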