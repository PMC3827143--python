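import numpy as np
import pytest

from fourcbricks.fragmap import FragmentMap, ViewpointSpec


@pytest.fixture
def small_map() -> FragmentMap:
    """10 fragments of irregular width tiling a 50 kb chromosome."""
    bounds = [0, 3_000, 7_500, 12_000, 18_000, 22_000, 29_000, 35_000, 41_000, 46_000, 50_000]
    return FragmentMap(
        chrom="chrT",
        starts=np.array(bounds[:-1]),
        ends=np.array(bounds[1:]),
    )


@pytest.fixture
def small_vp(small_map) -> ViewpointSpec:
    return ViewpointSpec(name="VP", chrom="chrT", position=100, exclusion_k=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
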