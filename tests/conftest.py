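import numpy as np
import pytest

from ihcscore import ODMatrix, RGBImage, SynthConfig, generate_cohort

#: Classical OD unit directions used as ground truth throughout the tests.
H_VEC = np.array([0.650, 0.704, 0.286])
D_VEC = np.array([0.269, 0.568, 0.778])
H_VEC = H_VEC / np.linalg.norm(H_VEC)
D_VEC = D_VEC / np.linalg.norm(D_VEC)


def angular_error_deg(w_est: np.ndarray, w_true: np.ndarray) -> list[float]:
    """Per-column angle (degrees) between estimated and true stain vectors."""
    out = []
    for s in range(w_true.shape[1]):
        a = w_est[:, s] / np.linalg.norm(w_est[:, s])
        b = w_true[:, s] / np.linalg.norm(w_true[:, s])
        out.append(float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0)))))
    return out


def make_od(values: np.ndarray) -> ODMatrix:
    """Wrap a raw 3xN array as an OD matrix (1-row raster)."""
    values = np.asarray(values, dtype=float)
    return ODMatrix(values, width=values.shape[1], height=1)


def random_mixture_od(
    rng: np.random.Generator, n: int = 400, dab_scale: float = 1.0
) -> tuple[ODMatrix, np.ndarray, np.ndarray]:
    """Noiseless rank-2 OD cloud X = W H with H >= 0; returns (od, W, H)."""
    w = np.column_stack([H_VEC, D_VEC])
    h = np.vstack(
        [rng.gamma(2.0, 0.4, size=n), dab_scale * rng.gamma(2.0, 0.4, size=n)]
    )
    return make_od(w @ h), w, h


@pytest.fixture(scope="session")
def default_cohort():
    """50-image default synthetic cohort (the end-to-end study conditions)."""
    return generate_cohort(SynthConfig(n_images=50, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """20-image noisy cohort for separation-level tests."""
    return generate_cohort(SynthConfig(n_images=20, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_image() -> RGBImage:
    arr = np.full((8, 8, 3), 200, dtype=np.uint8)
    return RGBImage.from_array(arr)
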