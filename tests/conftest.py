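import numpy as np
import pytest

from mechcomp import PointScene, SceneGeometry
from mechcomp import synthetic as syn


@pytest.fixture(scope="session")
def disc_geometry():
    return SceneGeometry(shape="disc", diameter=800.0, pixel_size=0.65, frame_interval=2.0)


@pytest.fixture(scope="session")
def rect_geometry():
    return SceneGeometry(shape="rectangle", width=200.0, height=150.0, pixel_size=1.0, frame_interval=0.5)


@pytest.fixture
def small_scene(rect_geometry):
    """Nine well-separated cells on a 200x150 um field."""
    xs, ys = np.meshgrid([40.0, 100.0, 160.0], [30.0, 75.0, 120.0])
    n = xs.size
    return PointScene(
        cell_id=np.arange(n),
        x=xs.ravel(),
        y=ys.ravel(),
        population=np.full(n, "cell", dtype=object),
        geometry=rect_geometry,
    )


def inset_monolayer(size_um, margin_um, density, min_spacing, seed):
    """Monolayer on a size x size field with all cells >= margin from the
    border (so rendered spots are unclipped and detectable)."""
    inner = SceneGeometry(
        shape="rectangle",
        width=size_um - 2 * margin_um,
        height=size_um - 2 * margin_um,
        pixel_size=1.0,
        frame_interval=1.0,
    )
    scene = syn.make_monolayer(inner, density, min_spacing, seed=seed)
    outer = SceneGeometry(
        shape="rectangle", width=size_um, height=size_um, pixel_size=1.0, frame_interval=1.0
    )
    return PointScene(
        cell_id=scene.cell_id,
        x=scene.x + margin_um,
        y=scene.y + margin_um,
        population=scene.population,
        geometry=outer,
    )


@pytest.fixture(scope="session")
def rendered_hundred():
    """Noiseless render of 100 well-spaced nuclei plus its ground truth."""
    inner_area = 280.0 * 280.0 / 1e4
    scene = inset_monolayer(300.0, 10.0, 100 / inner_area, 12.0, seed=11)
    assert scene.n_cells == 100
    stack = syn.render_images(scene, psf_sigma_px=2.0, noise_model=None, seed=0)
    return stack, scene
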