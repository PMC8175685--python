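import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from zygosim.optics import OpticsConfig, build_defocus_lut, render_image
from zygosim.scene import (GeneratorConfig, Nucleolus, Pronucleus, ZygoteScene,
                           sample_scene)


@pytest.fixture(scope="session")
def nf_optics():
    """Noise-free rendering optics on a 256 px field (zygote still fits)."""
    return OpticsConfig(pixel_noise_sigma=0.0, image_size=(256, 256))


@pytest.fixture(scope="session")
def lut(nf_optics):
    return build_defocus_lut(nf_optics)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_nucleolus_scene(dz_um=0.0, radius_um=4.0, xy_um=(0.0, 0.0),
                           pn_radius=11.0):
    """Centred zygote with one nucleolus at a controlled height/offset."""
    x, y = xy_um
    return ZygoteScene(
        zygote_id="fixture",
        center=np.zeros(3),
        cytoplasm_radius=40.0,
        zona_thickness=10.0,
        pronuclei=[Pronucleus(
            center_offset=np.array([x, y, dz_um]),
            radius=pn_radius,
            nucleoli=[Nucleolus(center_offset=np.zeros(3), radius=radius_um)],
        )],
    )


def small_field_scene(nucleolus_xy_um, nucleolus_r_um, dz_um=0.0):
    """A compact zygote that fits a 128 px field at 0.5 um/px."""
    x, y = nucleolus_xy_um
    return ZygoteScene(
        zygote_id="small",
        center=np.zeros(3),
        cytoplasm_radius=24.0,
        zona_thickness=6.0,
        pronuclei=[Pronucleus(
            center_offset=np.array([x, y, dz_um]),
            radius=9.0,
            nucleoli=[Nucleolus(center_offset=np.zeros(3),
                                radius=nucleolus_r_um)],
        )],
    )


@pytest.fixture
def render_nf(nf_optics):
    def _render(scene, focus_z=0.0, **overrides):
        return render_image(scene, replace(nf_optics, focus_z=focus_z,
                                           **overrides))
    return _render
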