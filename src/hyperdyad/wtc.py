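"""Continuous Morlet wavelet transform and wavelet transform coherence.

The transform follows the standard analytic-Morlet formulation (centre
frequency ``omega0``, default 6) on a dyadic scale grid with a fixed
number of voices per octave.  Coherence is the smoothed magnitude-
squared cross-spectrum ratio

    R2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

with S a scale-dependent Gaussian smoother in time (std = s seconds)
followed by a boxcar across scales.  The cone of influence (COI) is the
e-folding time sqrt(2) * s of the wavelet at each scale; points closer
to an edge than the COI are flagged for exclusion from averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MorletGrid", "CoherenceMap", "cwt_morlet", "wtc", "SmoothingKernel"]

_FOURIER_FACTOR_CACHE: dict[float, float] = {}


def fourier_factor(omega0: float) -> float:
    """Ratio of Fourier period to wavelet scale for the Morlet wavelet."""
    if omega0 not in _FOURIER_FACTOR_CACHE:
        _FOURIER_FACTOR_CACHE[omega0] = 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))
    return _FOURIER_FACTOR_CACHE[omega0]


@dataclass(frozen=True)
class MorletGrid:
    """Dyadic scale grid covering a frequency range at ``fs`` Hz."""

    fs: float
    freq_range: tuple[float, float]
    scales_per_octave: int = 12
    omega0: float = 6.0

    @property
    def dj(self) -> float:
        return 1.0 / self.scales_per_octave

    @property
    def scales_s(self) -> np.ndarray:
        """Scales in seconds, increasing (frequencies decreasing)."""
        lo, hi = self.freq_range
        ff = fourier_factor(self.omega0)
        s0 = 1.0 / (hi * ff)
        n = int(np.ceil(np.log2((1.0 / (lo * ff)) / s0) / self.dj)) + 1
        return s0 * 2.0 ** (self.dj * np.arange(n))

    @property
    def freqs_hz(self) -> np.ndarray:
        return 1.0 / (self.scales_s * fourier_factor(self.omega0))

    def validate(self) -> None:
        lo, hi = self.freq_range
        if not (0 < lo < hi <= self.fs / 2 + 1e-12):
            raise ValueError(
                f"frequency range {self.freq_range} outside (0, fs/2] at fs={self.fs}")


def cwt_morlet(x: np.ndarray, grid: MorletGrid):
    """Continuous Morlet transform.

    Returns ``(w, coi_s)`` where ``w`` has shape (n_scales, n_t) (scales
    ordered by decreasing frequency) and ``coi_s[t]`` is the largest
    scale (seconds) still uncontaminated by edge effects at sample t.
    """
    grid.validate()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("cwt_morlet expects a 1-D series")
    n = len(x)
    if n < 32:
        raise ValueError("series too short for a meaningful transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    dt = 1.0 / grid.fs
    scales = grid.scales_s
    npad = int(2 ** np.ceil(np.log2(n) + 1))
    xf = np.fft.fft(x - x.mean(), npad)
    omega = 2 * np.pi * np.fft.fftfreq(npad, dt)
    w = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi ** -0.25
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        pos = omega > 0
        psi_hat[pos] = (norm_const * np.sqrt(2 * np.pi * s / dt)
                        * np.exp(-0.5 * (s * omega[pos] - grid.omega0) ** 2))
        w[i] = np.fft.ifft(xf * psi_hat)[:n]
    # distance to the nearest edge in seconds, divided by the e-folding factor
    t_idx = np.arange(n)
    edge_dist = np.minimum(t_idx, n - 1 - t_idx) * dt
    coi_s = edge_dist / np.sqrt(2.0)
    return w, coi_s


class SmoothingKernel:
    """Precomputed scale-dependent time smoother plus scale boxcar.

    Time smoothing convolves each scale row with a unit-sum Gaussian of
    standard deviation equal to the scale (in samples); the convolution
    is linear (zero-padded) and evaluated by FFT for all rows at once.
    Scale smoothing is a boxcar over ``0.6 / (2 dj)`` voices either side.
    """

    def __init__(self, grid: MorletGrid, n_t: int):
        self.grid = grid
        self.n_t = n_t
        scales_samp = grid.scales_s * grid.fs
        half = int(np.ceil(8 * scales_samp.max()))
        self.nfft = int(2 ** np.ceil(np.log2(n_t + 2 * half + 1)))
        k = np.arange(-half, half + 1)
        self.half = half
        kf = np.empty((len(scales_samp), self.nfft // 2 + 1), dtype=complex)
        for i, ss in enumerate(scales_samp):
            g = np.exp(-0.5 * (k / ss) ** 2)
            g /= g.sum()
            kern = np.zeros(self.nfft)
            kern[: 2 * half + 1] = g
            kf[i] = np.fft.rfft(kern)
        self._kf = kf
        m = int(np.floor(0.6 / (2 * grid.dj)))
        self.scale_halfwidth = m

    def smooth(self, arr: np.ndarray) -> np.ndarray:
        """Apply time then scale smoothing to (n_scales, n_t) data
        (real or complex)."""
        out = self._smooth_time(arr)
        return self._smooth_scale(out)

    def _smooth_time(self, arr):
        if np.iscomplexobj(arr):
            return (self._smooth_time(arr.real)
                    + 1j * self._smooth_time(arr.imag))
        af = np.fft.rfft(arr, self.nfft, axis=1)
        sm = np.fft.irfft(af * self._kf, self.nfft, axis=1)
        # 'same' alignment: kernel centre sits at index `half`
        return sm[:, self.half: self.half + self.n_t]

    def _smooth_scale(self, arr):
        m = self.scale_halfwidth
        if m == 0:
            return arr
        n_s = arr.shape[0]
        out = np.empty_like(arr)
        csum = np.cumsum(arr, axis=0)
        for i in range(n_s):
            lo, hi = max(0, i - m), min(n_s - 1, i + m)
            total = csum[hi] - (csum[lo - 1] if lo > 0 else 0)
            out[i] = total / (hi - lo + 1)
        return out


@dataclass
class CoherenceMap:
    """Squared wavelet coherence on the scale x time plane."""

    coherence: np.ndarray   # (n_scales, n_t) in [0, 1]
    freqs_hz: np.ndarray    # decreasing with scale index
    coi_s: np.ndarray       # (n_t,) largest valid scale in seconds
    scales_s: np.ndarray
    fs: float

    def valid_mask(self) -> np.ndarray:
        """(n_scales, n_t) True where the point lies inside the COI
        (scale not larger than the local edge-distance bound)."""
        return self.scales_s[:, None] <= self.coi_s[None, :]


def wtc(x: np.ndarray, y: np.ndarray, fs: float,
        freq_range: tuple[float, float] = (0.01, 0.5), *,
        scales_per_octave: int = 12, omega0: float = 6.0,
        grid: MorletGrid | None = None,
        kernel: SmoothingKernel | None = None) -> CoherenceMap:
    """Wavelet transform coherence of two equal-length series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: coherence undefined")
    if grid is None:
        grid = MorletGrid(fs, freq_range, scales_per_octave, omega0)
    wx, coi = cwt_morlet(x, grid)
    wy, _ = cwt_morlet(y, grid)
    if kernel is None:
        kernel = SmoothingKernel(grid, len(x))
    inv_s = 1.0 / grid.scales_s[:, None]
    sxx = kernel.smooth(np.abs(wx) ** 2 * inv_s)
    syy = kernel.smooth(np.abs(wy) ** 2 * inv_s)
    sxy = kernel.smooth(wx * np.conj(wy) * inv_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.abs(sxy) ** 2 / (sxx * syy)
    r2 = np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)
    return CoherenceMap(r2, grid.freqs_hz, coi, grid.scales_s, fs)
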