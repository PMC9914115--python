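import numpy as np
import pytest

import washsem as w


@pytest.fixture(scope="session")
def uniform_truth():
    """Constant-parameter SEM phantom (r' = 0.2, beta = 0.9), noiseless."""
    return w.make_phantom_truth(
        r_mean=0.2, r_sd=0.0, beta_mean=0.9, beta_sd=0.0,
        snr=float("inf"), n_images=10, gas="F19", seed=3,
    )


@pytest.fixture(scope="session")
def noisy_truth():
    """Smooth-field SEM phantom at SNR 20 (default study conditions)."""
    return w.make_phantom_truth(
        r_mean=0.2, r_sd=0.02, beta_mean=0.9, beta_sd=0.02,
        snr=20.0, n_images=10, gas="F19", seed=3,
    )


@pytest.fixture(scope="session")
def uniform_series(uniform_truth):
    return w.simulate_washout(uniform_truth, model="sem")


@pytest.fixture(scope="session")
def noisy_series(noisy_truth):
    return w.simulate_washout(noisy_truth, model="sem")


def grid_oracle_deninger(n: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Brute-force fit of S0*(1-r)**n: exhaustive r grid, closed-form S0."""
    rs = np.arange(0.001, 1.0, 0.001)
    d = (1.0 - rs[:, None]) ** n[None, :]            # (R, N)
    s0 = (d * s[None, :]).sum(axis=1) / (d * d).sum(axis=1)
    sse = ((s0[:, None] * d - s[None, :]) ** 2).sum(axis=1)
    k = int(np.argmin(sse))
    return float(s0[k]), float(rs[k])


def grid_oracle_sem(n: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Brute-force fit of S0*exp(-(n r')**beta) on a coarse 2-D grid."""
    rps = np.arange(0.02, 0.61, 0.002)
    betas = np.arange(0.40, 1.0001, 0.002)
    RP, B = np.meshgrid(rps, betas, indexing="ij")
    arg = n[None, None, :] * RP[..., None]
    d = np.exp(-np.power(arg, B[..., None]))
    s0 = (d * s).sum(axis=-1) / (d * d).sum(axis=-1)
    sse = ((s0[..., None] * d - s) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(s0[i, j]), float(RP[i, j]), float(B[i, j])
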