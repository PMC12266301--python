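import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import facedefender as fd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def neutral_params() -> fd.SyntheticFaceParams:
    return fd.SyntheticFaceParams(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def neutral_face(neutral_params):
    """Noise-free neutral face: (image, landmarks)."""
    return fd.render_face(neutral_params)


@pytest.fixture(scope="session")
def avatar_face():
    return fd.make_avatar(fd.SyntheticFaceParams(seed=2))


@pytest.fixture(scope="session")
def clean_cohort():
    """Seeded healthy cohort of 200 measurement vectors."""
    cohort, labels = fd.generate_cohort(fd.CohortSpec(n=200, seed=11))
    return cohort, labels


@pytest.fixture(scope="session")
def fitted_benchmark(clean_cohort):
    cohort, _ = clean_cohort
    model = fd.BenchmarkModel.from_measurements(cohort)
    return model.fit(seed=7)


def make_landmarks(left_iris, right_iris, spread=30.0):
    """Minimal valid 52-point landmark set with iris groups centered on
    the given points; eyelid/brow points are laid out on circles."""
    left_iris = np.asarray(left_iris, dtype=float)
    right_iris = np.asarray(right_iris, dtype=float)
    pts = []
    groups = {}
    idx = 0
    for center, prefix in ((left_iris, "LEFT"), (right_iris, "RIGHT")):
        th = 2 * np.pi * np.arange(16) / 16
        lid = center + spread * np.column_stack([np.cos(th), -0.5 * np.sin(th)])
        iris = center + np.array([[0, 0], [3, 0], [-3, 0], [0, 3], [0, -3]], dtype=float)
        tb = np.linspace(-1, 1, 5)
        brow = center + np.column_stack([spread * tb, -spread * 0.8 - 3 * (1 - tb**2)])
        groups[f"{prefix}_EYELID"] = np.arange(idx, idx + 16)
        idx += 16
        groups[f"{prefix}_IRIS"] = np.arange(idx, idx + 5)
        idx += 5
        groups[f"{prefix}_BROW"] = np.arange(idx, idx + 5)
        idx += 5
        pts.extend([lid, iris, brow])
    points = np.vstack(pts)
    span = int(points.max() + 50)
    return fd.LandmarkSet(points, groups, (span, span))
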