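import pytest

import shearpoint as sp


@pytest.fixture(scope="session")
def huvec_chamber():
    return sp.HUVEC_CHAMBER


@pytest.fixture(scope="session")
def rendered_field():
    """One rendered field at the HUVEC optimum: scene + image, 150 cells."""
    scene = sp.sample_scene_at_shear(
        sp.HUVEC_MODEL, 15.0, 150, seed=7, image_shape_px=sp.suggested_image_shape(150)
    )
    image = sp.render(scene)
    return scene, image


@pytest.fixture(scope="session")
def segmented_field(rendered_field):
    scene, image = rendered_field
    masks = sp.segment_nuclei(image.data[0], scene.pixel_size_um)
    masks = sp.derive_cell_regions(masks, image.data[1])
    return scene, image, masks
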