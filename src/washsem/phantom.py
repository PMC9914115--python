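"""Digital lung phantom: dynamic gas wash-out / wash-in image series.

The phantom emulates 2-D projection images of a small-animal chest during a
multi-breath gas wash-out experiment.  Each wash-out breath of tracer-free
gas replaces a fraction ``r`` of the gas in every lung voxel, so the
noiseless magnitude signal decays with breath number ``n`` as either

* the two-parameter ventilation model ``S(n) = S0 * (1 - r)**n``
  (each breath replaces the fraction ``r`` of the resident gas), or
* the stretched-exponential model ``S(n) = S0 * exp(-(n * r')**beta)``
  where ``beta <= 1`` is a heterogeneity index (``beta = 1`` is
  mono-exponential; smaller values encode a broader distribution of
  per-voxel turnover rates).

Magnitude images carry Rician noise: i.i.d. complex Gaussian noise is added
to the noiseless signal and the magnitude is taken, producing the familiar
Rayleigh background floor.  The target SNR is defined at the baseline frame
as (in-mask mean of frame 0) / (Gaussian sigma per channel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomTruth",
    "WashoutSeries",
    "make_phantom_truth",
    "simulate_washout",
    "simulate_washin",
    "reverse_series",
]

GASES = ("He3", "Xe129", "F19")

#: smallest distance a clipped parameter keeps from its open bound
_EPS = 1e-3

#: width (in pixels) of the Gaussian kernel smoothing the parameter fields
_FIELD_SMOOTH_PX = 4.0

#: default phase-encode field of view: 40 mm over 64 pixels
DEFAULT_PIXEL_MM = 40.0 / 64.0


@dataclass
class PhantomTruth:
    """Ground-truth maps and noise specification for one synthetic series."""

    lung_mask: np.ndarray
    s0_map: np.ndarray
    r_map: np.ndarray
    rprime_map: np.ndarray
    beta_map: np.ndarray
    snr: float
    n_images: int
    seed: int
    gas: str = "F19"

    def __post_init__(self) -> None:
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        for name in ("s0_map", "r_map", "rprime_map", "beta_map"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.gas not in GASES:
            raise ValueError(f"gas must be one of {GASES}, got {self.gas!r}")
        if self.n_images < 3:
            raise ValueError("n_images must be >= 3 (model identifiability)")
        m = self.lung_mask
        for name, lo, hi in (("r_map", 0.0, 1.0), ("rprime_map", 0.0, 1.0)):
            vals = getattr(self, name)[m]
            if vals.size and (vals.min() <= lo or vals.max() >= hi):
                raise ValueError(f"{name} must lie in the open interval ({lo}, {hi}) in-mask")
        bvals = self.beta_map[m]
        if bvals.size and (bvals.min() <= 0.0 or bvals.max() > 1.0):
            raise ValueError("beta_map must lie in (0, 1] in-mask")
        for name in ("s0_map", "r_map", "rprime_map", "beta_map"):
            arr = getattr(self, name)
            if np.any(arr[~m] != 0.0):
                raise ValueError(f"{name} must be zero outside the lung mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lung_mask.shape


@dataclass
class WashoutSeries:
    """Ordered stack of 2-D magnitude images, one per breath."""

    frames: np.ndarray               # (n_images, ny, nx), non-negative
    breath_index: np.ndarray         # 0 .. N-1
    gas: str = "F19"
    order: str = "washout"           # or "washin"
    pixel_size_mm: float = DEFAULT_PIXEL_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.breath_index = np.asarray(self.breath_index, dtype=int)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_images, ny, nx) stack")
        if len(self.frames) != len(self.breath_index):
            raise ValueError("frames and breath_index lengths differ")
        if len(self.breath_index) and not np.array_equal(
            self.breath_index, np.arange(len(self.breath_index))
        ):
            raise ValueError("breath_index must be 0..N-1, strictly increasing")
        if self.order not in ("washout", "washin"):
            raise ValueError("order must be 'washout' or 'washin'")
        if np.any(self.frames < 0):
            raise ValueError("magnitude frames must be non-negative")

    @property
    def n_images(self) -> int:
        return len(self.frames)

    def bulk_mean(self, mask: np.ndarray) -> np.ndarray:
        """Mean in-mask signal per frame (the bulk decay curve)."""
        mask = np.asarray(mask, dtype=bool)
        return self.frames[:, mask].mean(axis=1)

    def time_reversed(self) -> "WashoutSeries":
        """Frame-order reversal (an involution); flips the order label."""
        return replace(
            self,
            frames=self.frames[::-1].copy(),
            breath_index=np.arange(self.n_images),
            order="washin" if self.order == "washout" else "washout",
        )


def _two_lobe_mask(shape: tuple[int, int]) -> np.ndarray:
    """Two elliptical 'lobes' centred in the grid, mimicking a coronal
    projection of left and right lung."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy = ny / 2.0
    mask = np.zeros(shape, dtype=bool)
    # lobe semi-axes and lateral offsets scale with the grid
    a, b = 0.31 * ny, 0.14 * nx
    for cx in (nx / 2.0 - 0.19 * nx, nx / 2.0 + 0.19 * nx):
        mask |= ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    return mask


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean: float,
    sd: float,
    upper: float,
) -> np.ndarray:
    """Spatially correlated Gaussian random field, clipped to (eps, upper]."""
    if sd == 0.0:
        return np.full(shape, mean)
    noise = gaussian_filter(rng.standard_normal(shape), _FIELD_SMOOTH_PX)
    noise /= noise.std()
    fld = mean + sd * noise
    return np.clip(fld, _EPS, upper)


def make_phantom_truth(
    shape: tuple[int, int] = (64, 64),
    r_mean: float = 0.22,
    r_sd: float = 0.02,
    beta_mean: float = 0.9,
    beta_sd: float = 0.02,
    snr: float = 20.0,
    n_images: int = 10,
    gas: str = "F19",
    seed: int = 0,
) -> PhantomTruth:
    """Build ground-truth parameter maps on a two-lobe lung mask.

    ``r_mean``/``r_sd`` parameterise both the ventilation map ``r`` and the
    apparent (stretched-exponential) map ``r'``; ``beta_mean``/``beta_sd``
    the heterogeneity index.  Fields are smoothed Gaussian random fields
    (kernel width 4 px), reproducible from ``seed``; zero-variance inputs
    give constant, seed-independent maps.
    """
    if len(shape) != 2 or min(shape) < 32:
        raise ValueError("shape must be 2-D with both dims >= 32")
    if not (0.0 < r_mean - 3 * r_sd and r_mean + 3 * r_sd < 1.0):
        raise ValueError("r_mean +/- 3*r_sd must stay inside (0, 1)")
    if not (0.0 < beta_mean <= 1.0) or beta_mean - 3 * beta_sd <= 0.0:
        raise ValueError("beta_mean must lie in (0, 1] with a positive 3-sd envelope")
    if n_images < 3:
        raise ValueError("n_images must be >= 3")

    mask = _two_lobe_mask(tuple(shape))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(0,))
    rng_r, rng_rp, rng_b = (np.random.default_rng(c) for c in ss.spawn(3))

    r_map = _smooth_field(rng_r, tuple(shape), r_mean, r_sd, 1.0 - _EPS)
    rprime_map = _smooth_field(rng_rp, tuple(shape), r_mean, r_sd, 1.0 - _EPS)
    beta_map = _smooth_field(rng_b, tuple(shape), beta_mean, beta_sd, 1.0)
    s0_map = np.ones(tuple(shape))

    for arr in (r_map, rprime_map, beta_map, s0_map):
        arr[~mask] = 0.0

    return PhantomTruth(
        lung_mask=mask,
        s0_map=s0_map,
        r_map=r_map,
        rprime_map=rprime_map,
        beta_map=beta_map,
        snr=float(snr),
        n_images=int(n_images),
        seed=int(seed),
        gas=gas,
    )


def noiseless_frames(truth: PhantomTruth, model: str) -> np.ndarray:
    """Noise-free signal stack for ``model`` in {'deninger', 'sem'}."""
    n = np.arange(truth.n_images, dtype=float)[:, None, None]
    m = truth.lung_mask
    if model == "deninger":
        decay = np.where(m, (1.0 - truth.r_map) ** n, 0.0)
    elif model == "sem":
        # 0**beta == 0 for beta > 0, so frame 0 is exactly S0
        arg = np.where(m, (n * truth.rprime_map), 0.0)
        decay = np.where(m, np.exp(-np.power(arg, truth.beta_map, where=m,
                                             out=np.zeros_like(arg))), 0.0)
    else:
        raise ValueError("model must be 'deninger' or 'sem'")
    return truth.s0_map[None] * decay


def _add_rician(frames: np.ndarray, truth: PhantomTruth, rng_key: int) -> np.ndarray:
    if not np.isfinite(truth.snr):
        return frames
    if truth.snr <= 0:
        raise ValueError("snr must be positive")
    sigma = truth.s0_map[truth.lung_mask].mean() / truth.snr
    ss = np.random.SeedSequence(entropy=int(truth.seed), spawn_key=(rng_key,))
    rng = np.random.default_rng(ss)
    re = frames + sigma * rng.standard_normal(frames.shape)
    im = sigma * rng.standard_normal(frames.shape)
    return np.hypot(re, im)


def simulate_washout(truth: PhantomTruth, model: str = "sem") -> WashoutSeries:
    """Simulate a wash-out series: monotone decay plus Rician noise.

    Frame 0 is the baseline (full tracer signal, equal to the S0 map before
    noise); the in-mask signal then decays strictly with breath number for
    any in-mask voxel, for either model.
    """
    frames = _add_rician(noiseless_frames(truth, model), truth, rng_key=1)
    return WashoutSeries(
        frames=frames,
        breath_index=np.arange(truth.n_images),
        gas=truth.gas,
        order="washout",
        meta={"model": model, "snr": truth.snr, "seed": truth.seed},
    )


def simulate_washin(truth: PhantomTruth, model: str = "sem") -> WashoutSeries:
    """Simulate a wash-in series: the time-reversed wash-out decay.

    The tracer signal accumulates breath by breath and reaches the full
    (baseline) level at the final frame, mirroring an acquisition in which
    the tracer is delivered rather than washed out.  Reversing the frame
    order with :func:`reverse_series` recovers a decay-ordered series.
    """
    clean = noiseless_frames(truth, model)[::-1]
    frames = _add_rician(clean, truth, rng_key=2)
    return WashoutSeries(
        frames=frames,
        breath_index=np.arange(truth.n_images),
        gas=truth.gas,
        order="washin",
        meta={"model": model, "snr": truth.snr, "seed": truth.seed},
    )


def reverse_series(series: WashoutSeries) -> WashoutSeries:
    """Reverse a wash-in series into decay order (frame k -> frame N-1-k).

    Only wash-in input is accepted: wash-out data are already decay-ordered
    and reversing them would silently break every downstream fit.
    """
    if series.order == "washout":
        raise ValueError("series is already in wash-out (decay) order")
    return series.time_reversed()


def default_n_images(gas: str) -> int:
    """Conventional frame count: baseline + 7 wash-in breaths for the
    hyperpolarized gases, baseline + 9 wash-out breaths for F19."""
    return 8 if gas in ("He3", "Xe129") else 10
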