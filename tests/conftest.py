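import numpy as np
import pytest

from fcsweep.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small cohort that renders in well under a second."""
    return SimulationConfig(
        grid_shape=(14, 14, 14), n_nodes=4, n_blocks=2,
        n_subjects=3, n_volumes=30, seed=7,
    )


def dense_smooth_oracle(volume, weights):
    """Brute-force 3D weighted average with drop-and-renormalize boundaries.

    Independent of the separable implementation: visits every voxel and every
    kernel tap, accumulating only in-bounds neighbors and dividing by the
    in-bounds weight sum.
    """
    wx, wy, wz = weights
    rx, ry, rz = (len(wx) - 1) // 2, (len(wy) - 1) // 2, (len(wz) - 1) // 2
    nx_, ny, nz = volume.shape
    out = np.zeros_like(volume, dtype=float)
    for i in range(nx_):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                wsum = 0.0
                for a in range(-rx, rx + 1):
                    ia = i + a
                    if not 0 <= ia < nx_:
                        continue
                    for b in range(-ry, ry + 1):
                        jb = j + b
                        if not 0 <= jb < ny:
                            continue
                        for c in range(-rz, rz + 1):
                            kc = k + c
                            if not 0 <= kc < nz:
                                continue
                            w = wx[a + rx] * wy[b + ry] * wz[c + rz]
                            acc += w * volume[ia, jb, kc]
                            wsum += w
                out[i, j, k] = acc / wsum
    return out
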