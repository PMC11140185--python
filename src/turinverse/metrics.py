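"""Noise injection and pattern similarity / accuracy measures.

Relative noise: ``s`` percent relative noise corrupts each concentration
grid with iid Gaussian noise of standard deviation ``s/100 * Rp``, where
``Rp = max - min`` is the range of that grid.  Both species are corrupted,
each scaled by its own range, and the original pattern is left untouched.

Pattern similarity: the 2D Fourier power spectrum (unnormalized numpy FFT,
so Parseval reads ``sum |F|^2 = N^2 * sum |grid|^2``) is averaged over
annuli of unit integer radius in frequency-pixel units, producing the
radially averaged power spectrum (RAPS).  The mean squared difference
between two RAPS curves (RAPSD) compares two patterns by structure --
wavelength content -- rather than by pixel positions, which depend on the
initial condition and not on the model parameters.  By default the DC bin
is excluded from RAPSD (it encodes only the mean level) and the spectrum is
taken on the u channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Pattern

__all__ = [
    "NoiseSpec",
    "RAPSProfile",
    "range_rp",
    "add_relative_noise",
    "mean_relative_error",
    "mean_absolute_error",
    "raps",
    "rapsd",
    "dominant_wavelength",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Relative noise level in percent plus the seed of its realization."""

    s: float
    seed: int = 0

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("relative noise s must be >= 0")


@dataclass(frozen=True)
class RAPSProfile:
    k: np.ndarray       # integer radial frequency bin centers, 0..N//2
    power: np.ndarray   # mean spectral power per annulus

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k))
        object.__setattr__(self, "power", np.asarray(self.power, float))
        if len(self.k) != len(self.power):
            raise ValueError("k and power lengths differ")


def range_rp(grid) -> float:
    """Range Rp = max - min of a concentration grid."""
    grid = np.asarray(grid, float)
    if grid.size == 0 or not np.all(np.isfinite(grid)):
        raise ValueError("grid must be non-empty and finite")
    return float(grid.max() - grid.min())


def add_relative_noise(pattern: Pattern, spec: NoiseSpec) -> Pattern:
    """Corrupt both channels with iid Gaussian noise, sigma = s/100 * Rp."""
    rng = np.random.default_rng(spec.seed)
    out = pattern.copy()
    if spec.s > 0:
        out.u = out.u + rng.normal(0.0, spec.s / 100.0 * range_rp(out.u),
                                   out.u.shape)
        out.v = out.v + rng.normal(0.0, spec.s / 100.0 * range_rp(out.v),
                                   out.v.shape)
    out.meta = dict(out.meta, noise_s=spec.s, noise_seed=spec.seed)
    return out


def mean_relative_error(beta_hat, beta_true) -> float:
    """(1/p) * sum_i |bh_i - b_i| / |b_i|."""
    bh = np.asarray(beta_hat, float)
    bt = np.asarray(beta_true, float)
    if bh.shape != bt.shape:
        raise ValueError("parameter vectors have different lengths")
    zero = np.flatnonzero(bt == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"true parameter(s) at index {zero.tolist()} are zero; "
            "relative error undefined")
    return float(np.mean(np.abs(bh - bt) / np.abs(bt)))


def mean_absolute_error(beta_hat, beta_true) -> float:
    """Secondary statistic: undivided mean absolute parameter difference."""
    bh = np.asarray(beta_hat, float)
    bt = np.asarray(beta_true, float)
    if bh.shape != bt.shape:
        raise ValueError("parameter vectors have different lengths")
    return float(np.mean(np.abs(bh - bt)))


def raps(grid) -> RAPSProfile:
    """Radially averaged 2D Fourier power spectrum of a square grid.

    No windowing and no mean subtraction: the DC bin carries the mean level
    and range trends, which are themselves informative.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError(f"expected a square grid, got {grid.shape}")
    n = grid.shape[0]
    power = np.abs(np.fft.fftshift(np.fft.fft2(grid))) ** 2
    c = n // 2  # index of zero frequency after fftshift
    ii, jj = np.indices(power.shape)
    r = np.rint(np.hypot(ii - c, jj - c)).astype(int)
    kmax = n // 2
    mask = r <= kmax
    sums = np.bincount(r[mask], weights=power[mask], minlength=kmax + 1)
    counts = np.bincount(r[mask], minlength=kmax + 1)
    return RAPSProfile(k=np.arange(kmax + 1), power=sums / counts)


def rapsd(p1: RAPSProfile, p2: RAPSProfile, include_dc: bool = False) -> float:
    """Mean squared difference between two RAPS curves.

    Bin 0 is excluded unless ``include_dc`` is set, so the comparison is
    about pattern structure, not mean concentration.
    """
    if len(p1.k) != len(p2.k) or np.any(p1.k != p2.k):
        raise ValueError("RAPS profiles computed on different bin grids")
    start = 0 if include_dc else 1
    d = p1.power[start:] - p2.power[start:]
    return float(np.mean(d * d))


def pattern_raps(pattern: Pattern, channel: str = "u") -> RAPSProfile:
    """RAPS of one channel of a pattern (u, the observed species, by default)."""
    return raps(getattr(pattern, channel))


def dominant_wavelength(grid, dx: float) -> float:
    """Wavelength (space units) of the strongest non-DC radial frequency bin.

    Used to set the initial width of RBF kernels, which must live on the
    scale of the pattern wavelength.
    """
    prof = raps(grid)
    k = int(np.argmax(prof.power[1:])) + 1
    n = np.asarray(grid).shape[0]
    return n * dx / k
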