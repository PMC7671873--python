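import numpy as np
import pytest

from onhmorph.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default noise-free phantom: (radial set, circles, ground truth)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Rotationally symmetric flat-reference phantom with closed-form truth:
    circular BMO (r = 800), rim shelf height 355 (> shelf extent guard),
    flat BM (depth 0), constant TRT 355, flat lamina at -440."""
    spec = PhantomSpec(
        bmo_a_um=800.0,
        bmo_b_um=800.0,
        bmo_tilt_deg=0.0,
        bmo_depth_um=0.0,
        rim_height_um=355.0,
        rim_shelf_um=400.0,
        trt_base_um=355.0,
        trt_slope_per_um=0.0,
        lamina_depth_um=440.0,
        lamina_bow_um=0.0,
    )
    return spec, make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20177)
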