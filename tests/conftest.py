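import numpy as np
import pytest

from tracerflow.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A fast 32^3-ish phantom for unit tests (default tracer diffusivity)."""
    return PhantomSpec.from_dict(dict(
        grid_shape=(32, 32, 24),
        spacing=(0.25, 0.25, 0.25),
        striatum_center_mm=(4.0, 4.0, 2.5),
        striatum_radius_mm=1.8,
        callosum_slab_mm=(1.0, 7.0, 1.0, 7.0, 4.0, 5.0),
        source=dict(center_mm=(4.0, 4.0, 2.5)),
        noise=dict(t1_sigma=0.0, dw_sigma=0.0),
    ))


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


def ball_mask(shape, spacing, center_mm, radius_mm):
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                        indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm ** 2
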