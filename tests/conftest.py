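import numpy as np
import pytest

from spinecorr.phantom import PhantomConfig, generate_phantom


def small_config(**overrides) -> PhantomConfig:
    """A scaled-down phantom for cheap tests (16x16 grid, 1 slice)."""
    params = dict(nx=24, ny=24, n_slices=1, n_volumes=60, tr=3.6,
                  wm_semiaxes=(7.0, 5.5), csf_semiaxes=(9.5, 7.5),
                  neck_margin=1, seed=0)
    params.update(overrides)
    return PhantomConfig(**params)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size phantom subject (motion-free volume + truth)."""
    return generate_phantom(PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free full-size phantom (neural signal only)."""
    return generate_phantom(PhantomConfig(seed=7).quiet())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def smooth_volume(nx=32, ny=32, ns=2, nt=5, seed=0):
    """A band-limited (Gaussian-blob) test volume with negligible energy
    at the spatial Nyquist frequency."""
    rng = np.random.default_rng(seed)
    xx, yy = np.mgrid[0:nx, 0:ny].astype(float)
    data = np.zeros((nx, ny, ns, nt))
    for s in range(ns):
        for t in range(nt):
            img = np.zeros((nx, ny))
            for _ in range(3):
                cx, cy = rng.uniform(8, nx - 8, 2)
                w = rng.uniform(6, 14)
                img += rng.uniform(50, 120) * np.exp(
                    -((xx - cx) ** 2 + (yy - cy) ** 2) / w)
            data[:, :, s, t] = img + 10.0
    return data
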