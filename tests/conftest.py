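import numpy as np
import pytest

from massgrader.synthetic_data import (
    CucumberGeometry,
    GeneratorConfig,
    RadiusProfile,
    generate_dataset,
)


@pytest.fixture(scope="session")
def desk_config() -> GeneratorConfig:
    return GeneratorConfig.desk()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, desk_config):
    """30 desk-scale images, 10 per grade, shared across tests."""
    out = tmp_path_factory.mktemp("tiny_ds")
    manifest = generate_dataset(
        30, (10, 10, 10), out, seed=123, gen_config=desk_config
    )
    return manifest


def straight_geometry(
    r_max: float = 15.0,
    length: float = 250.0,
    kind: str = "sine",
    exponent: float = 0.25,
    **kwargs,
) -> CucumberGeometry:
    """A straight-axis cucumber with a configurable radius profile."""
    pts = tuple((float(x), 0.0) for x in np.linspace(0.0, length, 7))
    defaults = dict(
        curvature_amplitude=0.0, has_flower=False, spine_density=0.0, hue_seed=1
    )
    defaults.update(kwargs)
    return CucumberGeometry(
        spine_control_points=pts,
        length=length,
        radius_profile=RadiusProfile(r_max, kind, exponent),
        **defaults,
    )
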