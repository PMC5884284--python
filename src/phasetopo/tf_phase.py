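"""Complex-Morlet decomposition and instantaneous phase extraction.

Channels are decomposed on a geometric grid of narrow bands (default 12
bands from 1 to 12 Hz) by convolution with unit-energy complex Morlet
wavelets whose Gaussian envelope spans a fixed number of cycles.  The
four-quadrant arctangent of the complex coefficients gives the
instantaneous phase per channel, sample and band; squared magnitudes give
per-channel time-frequency power maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "FrequencyGrid",
    "AnalyticTensor",
    "PhaseTensor",
    "PowerTensor",
    "center_frequencies",
    "morlet",
    "analytic_decompose",
    "instantaneous_phase",
    "power",
]

DEFAULT_CYCLES = 4.0


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class FrequencyGrid:
    """Geometric grid of band center frequencies.

    Centers are log-spaced so that consecutive ratios are constant and the
    endpoints hit ``fmin`` and ``fmax`` exactly:
    ``centers[k] = exp(ln fmin + (ln fmax - ln fmin) * k / (K - 1))``.
    """

    fmin: float
    fmax: float
    centers: tuple[float, ...]

    @property
    def n_bands(self) -> int:
        return len(self.centers)

    def rounded(self, decimals: int = 1) -> tuple[float, ...]:
        """Half-up rounded centers, used only for display labels."""
        return tuple(_round_half_up(c, decimals) for c in self.centers)

    def band_index(self, f: float) -> int:
        """Index of the band whose (rounded) center matches ``f`` best."""
        return int(np.argmin(np.abs(np.asarray(self.centers) - f)))


def center_frequencies(fmin: float, fmax: float, K: int) -> FrequencyGrid:
    """Build the K-band geometric frequency grid between fmin and fmax.

    With the default analysis settings (1 to 12 Hz, K = 12) the grid
    contains, after one-decimal rounding, the delta/theta band centers
    1.3, 1.6, 2.0, 2.5 and 3.1 Hz and the 7.6 Hz band.
    """
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    if K < 2:
        raise ValueError("need at least two bands")
    k = np.arange(K)
    centers = np.exp(np.log(fmin) + (np.log(fmax) - np.log(fmin)) * k / (K - 1))
    return FrequencyGrid(fmin, fmax, tuple(float(c) for c in centers))


def morlet(fk: float, cycles: float = DEFAULT_CYCLES, fs: float = 256.0) -> np.ndarray:
    """Discrete unit-energy complex Morlet wavelet at center frequency fk.

    ``Psi(t) = exp(i 2 pi fk t) exp(-t^2 / (2 sigma^2))`` sampled at
    ``t = n / fs`` over +-4 sigma, with the Gaussian standard deviation
    ``sigma = cycles / (2 pi fk)`` seconds, then normalized to unit energy.
    """
    if fk <= 0:
        raise ValueError("center frequency must be positive")
    if fk >= fs / 2:
        raise ValueError(f"band {fk} Hz is not resolvable at fs={fs} Hz")
    if cycles < 1:
        raise ValueError("need at least one wavelet cycle")
    sigma = cycles / (2.0 * math.pi * fk)
    half = int(round(4.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * math.pi * fk * t) * np.exp(-(t**2) / (2.0 * sigma**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


@dataclass
class AnalyticTensor:
    """Complex wavelet coefficients, channels x samples x bands.

    ``coi`` flags samples within 4 sigma of either record edge per band
    (cone of influence); coefficients there are edge-contaminated but are
    computed anyway and carried with the flag.
    """

    values: np.ndarray  # complex, (n_channels, n_samples, n_bands)
    fs: float
    grid: FrequencyGrid
    cycles: float
    coi: np.ndarray  # bool, (n_samples, n_bands); True = edge-contaminated


@dataclass
class PhaseTensor:
    """Instantaneous phase in (-pi, pi], channels x samples x bands."""

    values: np.ndarray
    fs: float
    grid: FrequencyGrid
    coi: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PowerTensor:
    """Squared wavelet magnitude, channels x samples x bands."""

    values: np.ndarray
    fs: float
    grid: FrequencyGrid
    coi: np.ndarray


def analytic_decompose(
    signals: np.ndarray,
    grid: FrequencyGrid,
    cycles: float = DEFAULT_CYCLES,
    fs: float = 256.0,
) -> AnalyticTensor:
    """Convolve every channel with every band's Morlet wavelet.

    Output has the same length as the input (zero-padded boundaries).  When
    a wavelet's nominal +-4 sigma support exceeds the record, the wavelet
    is truncated symmetrically to fit; records shorter than one cycle of
    the slowest band are rejected.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if n_samp < fs / grid.centers[0]:
        raise ValueError(
            "record is shorter than one cycle of the slowest analysis band"
        )
    values = np.empty((n_ch, n_samp, grid.n_bands), dtype=complex)
    coi = np.zeros((n_samp, grid.n_bands), dtype=bool)
    for k, fk in enumerate(grid.centers):
        w = morlet(fk, cycles, fs)
        if len(w) > n_samp:  # truncate support to the record, keep symmetry
            half = (n_samp - 1) // 2
            center = len(w) // 2
            w = w[center - half : center + half + 1]
            w = w / np.sqrt(np.sum(np.abs(w) ** 2))
        values[:, :, k] = fftconvolve(signals, w[None, :], mode="same", axes=1)
        edge = int(round(4.0 * cycles / (2.0 * math.pi * fk) * fs))
        coi[: min(edge, n_samp), k] = True
        coi[max(n_samp - edge, 0) :, k] = True
    return AnalyticTensor(values=values, fs=fs, grid=grid, cycles=cycles, coi=coi)


def instantaneous_phase(analytic: AnalyticTensor) -> PhaseTensor:
    """Four-quadrant arctangent of the coefficients, in (-pi, pi].

    A numerically zero coefficient maps to phase 0 (the atan2 convention).
    """
    return PhaseTensor(
        values=np.angle(analytic.values),
        fs=analytic.fs,
        grid=analytic.grid,
        coi=analytic.coi,
    )


def power(analytic: AnalyticTensor) -> PowerTensor:
    """Squared modulus of the coefficients per channel, sample and band."""
    return PowerTensor(
        values=np.abs(analytic.values) ** 2,
        fs=analytic.fs,
        grid=analytic.grid,
        coi=analytic.coi,
    )
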