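import numpy as np
import pytest

from cartstrain.phantom import PhantomSpec, generate_phantom, slice_to_contours
from cartstrain.surfaces import RadialSurface


def make_sphere_surface(radius: float = 10.0, center=(0.0, 0.0, 0.0)) -> RadialSurface:
    """Analytic full sphere as a radial surface."""
    return RadialSurface(
        center=np.asarray(center, dtype=float),
        radius_fn=lambda u: np.full(len(u), float(radius)),
        domain_fn=lambda u: np.ones(len(u), dtype=bool),
        r_bounds=(radius - 0.1, radius + 0.1),
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Default-geometry phantom: pre/post scenes and ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_stacks(default_phantom):
    """Noisy (0.04 mm) pre/post contour stacks of the default phantom."""
    pre_scene, post_scene, truth = default_phantom
    spec = PhantomSpec()
    pre = slice_to_contours(pre_scene, spec.contour_slice_spacing,
                            spec.in_plane_point_spacing, spec.noise_sd, seed=101,
                            subject="default")
    post = slice_to_contours(post_scene, spec.contour_slice_spacing,
                             spec.in_plane_point_spacing, spec.noise_sd, seed=202,
                             subject="default")
    return pre, post, truth


@pytest.fixture(scope="session")
def glenoid_scene():
    """Glenoid-only phantom scene (faster than the full shoulder)."""
    return generate_phantom(PhantomSpec(compartments=("glenoid",)))
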