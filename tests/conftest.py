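import pytest

from famsv.sv_io import CohortManifest, SVCall


@pytest.fixture
def manifest() -> CohortManifest:
    """The study layout: 10 probands, 5 unaffected relatives."""
    return CohortManifest.default(10, 5)


def make_call(chrom="chr1", start=1000, length=100, svtype="DEL",
              sample="S1", caller="c1", **kw) -> SVCall:
    return SVCall(chrom, start, length, svtype, sample, caller, **kw)


@pytest.fixture
def call_factory():
    return make_call
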