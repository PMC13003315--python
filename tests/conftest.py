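import pytest

from epiquant.simulate import TissueParams, generate_tissue


@pytest.fixture(scope="session")
def flat_bundle():
    """Default desk-scale flat tissue (50 cells, seed 1)."""
    return generate_tissue(TissueParams(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """Smaller tissue for fast module-level checks."""
    return generate_tissue(
        TissueParams(shape=(32, 160, 160), n_cells=25, seed=3)
    )


@pytest.fixture(scope="session")
def curved_bundle():
    """10 µm dome: the curved regime where Z-projection assignment fails."""
    return generate_tissue(TissueParams(seed=1, curvature=10.0))
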