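import numpy as np
import pytest

from bonegrad import morphometry as mm
from bonegrad import segmentation as seg
from bonegrad import synthetic_data as sd


def tiny_spec(seed: int = 7, porosity: float = 0.15, diameter: float = 60.0, **kw):
    """A fast, fully featured shell phantom (~0.3 Mvoxel)."""
    defaults = dict(
        outer_radius=300.0,
        inner_radius=120.0,
        length=600.0,
        voxel_size=10.0,
        wall_gain=0.0,
        porosity_profile=lambda s, d: porosity,
        diameter_profile=lambda s, d: diameter,
        min_diameter=25.0,
        band_length=600.0,
        seed=seed,
    )
    defaults.update(kw)
    return sd.PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Noise-free tiny phantom with its full measurement stack."""
    gray, truth = sd.generate_cortical_phantom(tiny_spec())
    mask = seg.despeckle_2d(seg.global_threshold(gray))
    env = mm.build_envelope(mask, closing_radius=100.0)
    cav = mm.medullary_cavity(mask, env)
    void = mm.intracortical_void(mask, env, cav)
    tmap = mm.local_thickness(void)
    return {
        "gray": gray, "truth": truth, "mask": mask,
        "envelope": env, "cavity": cav, "void": void, "tmap": tmap,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
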