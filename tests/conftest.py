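import numpy as np
import pytest

from tamponade import (EyeGeometryParams, FluidProperties, Posture, Variant,
                       build_eye_surface, label_regions)


@pytest.fixture(scope="session")
def params():
    return EyeGeometryParams()


@pytest.fixture(scope="session")
def fluids():
    return FluidProperties()


@pytest.fixture(scope="session")
def standing():
    return Posture.from_name("standing")


@pytest.fixture(scope="session")
def labelled_variants(params):
    """(mesh, region map) for each of the three chamber morphologies."""
    out = {}
    for variant in Variant:
        mesh = build_eye_surface(params, variant)
        out[variant] = (mesh, label_regions(mesh, params, variant))
    return out


@pytest.fixture(scope="session")
def near_sphere():
    """A chamber with a vanishing lens cap: analytically a full sphere."""
    p = EyeGeometryParams(lens_cap_height=1e-6)
    mesh = build_eye_surface(p, Variant.EMMETROPIC)
    return p, mesh, label_regions(mesh, p)
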