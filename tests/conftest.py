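import numpy as np
import pytest

from neogrowth import ChannelSpec, channel_sdf, initial_levelset
from neogrowth.fields import LevelSetState, ScalarField


@pytest.fixture(scope="session")
def circle_state():
    """Circular channel d = 1 mm, no initial layer, spacing d/50."""
    psi = channel_sdf(ChannelSpec("circle", 1.0), spacing=0.02)
    return initial_levelset(psi, 0.0)


@pytest.fixture(scope="session")
def triangle_state():
    psi = channel_sdf(ChannelSpec("triangle", 1.0), spacing=0.02)
    return initial_levelset(psi, 0.0)


def radial_phi(r_void: float, half_extent: float, spacing: float, dim: int = 2):
    """Exact signed distance of a circular/spherical void of radius r_void
    (tissue outside: φ = r − r_void)."""
    n = int(round(2 * half_extent / spacing)) + 1
    ax = -half_extent + spacing * np.arange(n)
    mesh = np.meshgrid(*([ax] * dim), indexing="ij")
    r = np.sqrt(sum(m**2 for m in mesh))
    phi = ScalarField(r - r_void, spacing, (-half_extent,) * dim)
    return LevelSetState(
        phi, 0.0, void0_mask=(r < r_void), meta={"geometry_id": f"radial{dim}d"}
    )
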