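"""Cartesian k-space transforms and retrospective under-sampling.

Conventions: the DC sample sits at the grid centre (``fftshift`` layout),
the phase-encode direction is the first image axis (rows), and the readout
direction (columns) is fully sampled for the full-echo (FGRE) scheme.  The
centred 2-D DFT is orthonormal, so forward/inverse round trips are exact to
floating point.

Under-sampling keeps ``ceil(n_lines / AF)`` phase-encode lines per breath
(AF = 10 keeps 7 of 64, AF = 14 keeps 5), drawn without replacement from a
triangular centre-weighted density.  The DC line is always kept and edge
lines remain eligible; an independent draw per breath yields the varying
sparsity pattern that joint reconstruction exploits.

The half-echo (X-Centric) acquisition records only ~50.5% of each readout
window starting at the echo centre; a second pass with opposite readout
polarity records the complementary half.  On simulated data the two halves
merge losslessly, so the scheme is represented by the exact split/merge
pair plus a phase-encode pattern drawn from a scheme-specific seed stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import WashoutSeries

__all__ = [
    "KSpaceSeries",
    "SamplingMask",
    "lines_for_af",
    "make_sampling_mask",
    "forward_kspace",
    "apply_mask",
    "split_xcentric",
    "merge_xcentric",
]


@dataclass
class KSpaceSeries:
    """Complex Cartesian k-space per breath (DC at the grid centre)."""

    frames: np.ndarray                 # (n_images, ny, nx) complex
    pe_axis: int = 0                   # image axis that is phase-encode
    dc_index: tuple[int, int] = (0, 0)
    observed: np.ndarray | None = None  # bool, same shape; None = all observed
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=complex)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_images, ny, nx)")
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.frames.shape:
                raise ValueError("observed mask shape mismatch")

    @property
    def n_images(self) -> int:
        return len(self.frames)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SamplingMask:
    """Per-breath binary phase-encode line patterns."""

    pattern: np.ndarray        # (n_images, n_pe) uint8
    af: float
    scheme: str                # 'fgre' | 'xcentric'
    seed: int

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=np.uint8)
        if self.pattern.ndim != 2:
            raise ValueError("pattern must be (n_images, n_pe)")
        if self.scheme not in ("fgre", "xcentric"):
            raise ValueError("scheme must be 'fgre' or 'xcentric'")
        if self.af < 1:
            raise ValueError("af must be >= 1")

    @property
    def n_images(self) -> int:
        return self.pattern.shape[0]

    @property
    def n_pe(self) -> int:
        return self.pattern.shape[1]

    def lines(self, breath: int) -> np.ndarray:
        return np.flatnonzero(self.pattern[breath])


def lines_for_af(af: float, n_lines: int) -> int:
    """Number of retained phase-encode lines: ``ceil(n_lines / af)``."""
    if af < 1:
        raise ValueError("af must be >= 1")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    return math.ceil(n_lines / af - 1e-12)


def make_sampling_mask(
    n_images: int,
    n_pe_lines: int,
    af: float,
    scheme: str = "fgre",
    seed: int = 0,
) -> SamplingMask:
    """Draw per-breath line patterns from a centre-weighted density.

    The density is triangular with its peak at the DC line; the DC line is
    always included and every other line (including the k-space edges) is
    eligible.  Patterns are drawn independently per breath, so for AF > 1
    they differ across breaths almost surely.  The X-Centric scheme uses a
    seed stream distinct from FGRE so the two schemes produce distinct
    patterns for the same seed.
    """
    if scheme not in ("fgre", "xcentric"):
        raise ValueError("scheme must be 'fgre' or 'xcentric'")
    keep = lines_for_af(af, n_pe_lines)
    if keep < 2 and af > 1:
        raise ValueError("fewer than 2 retained lines; lower the AF")
    pattern = np.zeros((n_images, n_pe_lines), dtype=np.uint8)
    if keep >= n_pe_lines:
        pattern[:] = 1
        return SamplingMask(pattern, float(af), scheme, int(seed))

    dc = n_pe_lines // 2
    idx = np.arange(n_pe_lines)
    weights = n_pe_lines / 2.0 + 1.0 - np.abs(idx - dc)   # triangular, peak at DC
    weights = np.clip(weights, 1.0, None)                 # edges stay eligible
    weights[dc] = 0.0                                     # DC is forced, not drawn
    prob = weights / weights.sum()

    stream = 0 if scheme == "fgre" else 1
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,))
    rng = np.random.default_rng(ss)
    for b in range(n_images):
        chosen = rng.choice(idx, size=keep - 1, replace=False, p=prob)
        pattern[b, chosen] = 1
        pattern[b, dc] = 1
    return SamplingMask(pattern, float(af), scheme, int(seed))


def _centered_fft2(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho", axes=(-2, -1)),
        axes=(-2, -1),
    )


def _centered_ifft2(ksp: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho", axes=(-2, -1)),
        axes=(-2, -1),
    )


def forward_kspace(series: WashoutSeries) -> KSpaceSeries:
    """Centred orthonormal 2-D DFT of each frame."""
    if not np.all(np.isfinite(series.frames)):
        raise ValueError("frames must be finite")
    frames = _centered_fft2(series.frames.astype(float))
    ny, nx = frames.shape[1:]
    return KSpaceSeries(
        frames=frames,
        pe_axis=0,
        dc_index=(ny // 2, nx // 2),
        observed=None,
        meta={"gas": series.gas, "order": series.order,
              "pixel_size_mm": series.pixel_size_mm},
    )


def hann_window(shape: tuple[int, int]) -> np.ndarray:
    """Separable 2-D raised-cosine window with peak exactly 1 at the DC
    sample of the shifted grid (index N//2 per axis)."""
    wins = []
    for n in shape:
        k = np.arange(n)
        wins.append(0.5 * (1.0 + np.cos(2.0 * np.pi * (k - n // 2) / n)))
    return np.outer(wins[0], wins[1])


def apply_mask(kspace: KSpaceSeries, mask: SamplingMask, hann: bool = False) -> KSpaceSeries:
    """Zero the unsampled phase-encode lines and flag them unobserved.

    With ``hann=True`` the 2-D raised-cosine window (an SNR-boosting
    apodization, peak 1 at DC) multiplies each frame *before* masking, as
    done for low-SNR fluorinated-gas data.
    """
    ny, nx = kspace.grid_shape
    if mask.n_images != kspace.n_images or mask.n_pe != ny:
        raise ValueError("mask dimensions do not match the k-space series")
    frames = kspace.frames.copy()
    if hann:
        frames *= hann_window((ny, nx))[None]
    observed = np.repeat(mask.pattern.astype(bool)[:, :, None], nx, axis=2)
    frames[~observed] = 0.0
    meta = dict(kspace.meta)
    meta.update({"af": mask.af, "scheme": mask.scheme, "hann": bool(hann)})
    return replace(kspace, frames=frames, observed=observed, meta=meta)


def _half_slices(n_read: int) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of the two opposite-polarity half-echoes along readout.

    Each half holds ``n_read // 2 + 1`` samples (33 of 64, i.e. just over
    half the readout window) and both contain the DC column.
    """
    dc = n_read // 2
    neg = np.arange(0, dc + 1)            # low-frequency edge .. DC
    pos = np.arange(dc - 1, n_read)       # DC-1 .. high-frequency edge
    return pos, neg


def split_xcentric(kspace: KSpaceSeries) -> tuple[KSpaceSeries, KSpaceSeries]:
    """Split full k-space into two opposite-polarity half-echo acquisitions."""
    ny, nx = kspace.grid_shape
    pos_idx, neg_idx = _half_slices(nx)
    out = []
    for idx in (pos_idx, neg_idx):
        cover = np.zeros(nx, dtype=bool)
        cover[idx] = True
        observed = np.broadcast_to(cover, kspace.frames.shape).copy()
        frames = np.where(observed, kspace.frames, 0.0)
        out.append(replace(kspace, frames=frames, observed=observed))
    return out[0], out[1]


def merge_xcentric(k_pos: KSpaceSeries, k_neg: KSpaceSeries) -> KSpaceSeries:
    """Assemble full readout lines from two complementary half-echoes.

    Requires each half to declare its coverage, to contain the DC column,
    and the union to cover the whole readout; where both halves observed a
    sample (at least the DC column) their mean is taken.  On noiseless
    simulated halves the merge reproduces the original k-space exactly.
    """
    if k_pos.observed is None or k_neg.observed is None:
        raise ValueError("both halves must carry an 'observed' coverage mask")
    if k_pos.frames.shape != k_neg.frames.shape:
        raise ValueError("half-echo shapes differ")
    dc_col = k_pos.dc_index[1]
    for half in (k_pos, k_neg):
        if not half.observed[..., dc_col].all():
            raise ValueError("each half-echo must include the DC sample")
    union = k_pos.observed | k_neg.observed
    if not union.all():
        raise ValueError("half-echoes do not cover the full readout window")
    count = k_pos.observed.astype(int) + k_neg.observed.astype(int)
    total = np.where(k_pos.observed, k_pos.frames, 0.0) + np.where(
        k_neg.observed, k_neg.frames, 0.0
    )
    frames = total / count
    return replace(k_pos, frames=frames, observed=None)
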