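"""Plane-wave superposition of signaling vs. pumping pump pools.

The cell-surface Na/K-ATPase is pictured as two spatially and
spectrally separated pools: a "signaling" pool (caveolar, complexed
with caveolin-1 and Src, cycling slowly) and a "pumping" pool (the
bulk transporters, cycling fast).  Each pool is a complex plane wave

    psi(x, t) = A * exp(i * (2*pi*f*t - k*x + phase))

on its own spatial domain, zero elsewhere; the real part tracks the
E1 <-> E2 transition coordinate and the imaginary part the
phosphorylation step.  Defaults: signaling pool on the first 250
arbitrary length units at 150 Hz, pumping pool on the next 500 units
at 500 Hz.

A Fourier power spectrum along time (periodograms averaged over space)
separates the pools into two peaks.  The lower, signaling-pool peak is
read as net Src inhibition; ouabain binding, which shifts pumps toward
the E2 state and releases Src, is modelled as a fractional loss of
signaling-pool amplitude and shows up as a diminished signaling peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np


class WaveError(ValueError):
    pass


@dataclass(frozen=True)
class PoolConfig:
    """One pump pool: spatial extent, temporal frequency, amplitude, phase."""

    name: str
    spatial_extent: float
    frequency: float
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self):
        if self.frequency <= 0 or self.spatial_extent <= 0:
            raise WaveError("frequency and spatial_extent must be positive")
        if self.amplitude < 0:
            raise WaveError("amplitude must be non-negative")


def default_pools() -> list[PoolConfig]:
    """Signaling pool (250 units, 150 Hz) + pumping pool (500 units, 500 Hz)."""
    return [
        PoolConfig("signaling", spatial_extent=250.0, frequency=150.0),
        PoolConfig("pumping", spatial_extent=500.0, frequency=500.0),
    ]


def apply_ouabain_shift(pools: list[PoolConfig], shift_fraction: float) -> list[PoolConfig]:
    """Shift of the E2:E1 balance by ouabain binding.

    A fraction ``shift_fraction`` of the signaling pool leaves the
    Src-inhibiting E1 state, so the signaling-pool amplitude is scaled
    by (1 - shift_fraction); pumping pools are unchanged.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise WaveError("shift_fraction must be in [0, 1]")
    out = []
    for pool in pools:
        if pool.name == "signaling":
            out.append(replace(pool, amplitude=pool.amplitude * (1.0 - shift_fraction)))
        else:
            out.append(pool)
    return out


@dataclass(frozen=True)
class WaveField:
    """Complex field psi(x, t) on a rectangular (space x time) grid."""

    space_grid: np.ndarray
    time_grid: np.ndarray
    values: np.ndarray  # shape (n_space, n_time), complex
    pools: tuple[PoolConfig, ...] = ()

    def __post_init__(self):
        if self.values.shape != (len(self.space_grid), len(self.time_grid)):
            raise WaveError("field shape does not match grids")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time_grid[1] - self.time_grid[0])

    def mean_square(self) -> float:
        """Spatially averaged time-domain mean |psi|^2."""
        return float(np.mean(np.abs(self.values) ** 2))


#: Defaults give 1 Hz bins over a 1 s window, Nyquist-safe for 500 Hz.
DEFAULT_DURATION = 1.0
DEFAULT_SAMPLING_RATE = 4096.0
DEFAULT_DX = 1.0


def build_field(
    pools: list[PoolConfig],
    duration: float = DEFAULT_DURATION,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    dx: float = DEFAULT_DX,
) -> WaveField:
    """Superpose the pools' plane waves on disjoint spatial domains.

    Pool domains are laid end to end in list order.  The time grid must
    resolve every configured frequency (sampling_rate > 2 * max f), else
    a :class:`WaveError` names the required rate.
    """
    if not pools:
        raise WaveError("need at least one pool")
    fmax = max(p.frequency for p in pools)
    if sampling_rate <= 2.0 * fmax:
        raise WaveError(
            f"sampling rate {sampling_rate} Hz violates Nyquist for "
            f"{fmax} Hz; need > {2.0 * fmax} Hz"
        )
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    total_extent = sum(p.spatial_extent for p in pools)
    x = np.arange(0.0, total_extent, dx)
    values = np.zeros((len(x), len(t)), dtype=complex)
    x0 = 0.0
    for pool in pools:
        mask = (x >= x0) & (x < x0 + pool.spatial_extent)
        if pool.amplitude > 0:
            k = 2.0 * np.pi / pool.spatial_extent  # one wavelength per domain
            phase = (
                2.0 * np.pi * pool.frequency * t[None, :]
                - k * (x[mask, None] - x0)
                + pool.phase
            )
            values[mask, :] = pool.amplitude * np.exp(1j * phase)
        x0 += pool.spatial_extent
    return WaveField(x, t, values, tuple(pools))


@dataclass(frozen=True)
class PowerSpectrum:
    """Spatially averaged periodogram along the time axis."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        if np.any(self.power < 0):
            raise WaveError("spectral power must be non-negative")

    def total_power(self) -> float:
        return float(self.power.sum())


def power_spectrum(field: WaveField) -> PowerSpectrum:
    """Discrete Fourier power of the field, averaged over positions.

    Power per bin is |X_k|^2 / N^2, so the sum over all bins equals the
    time-domain mean square amplitude (Parseval).  No window is applied
    (plain rectangular FFT).  The frequency axis is returned in
    ascending order including negative frequencies; a purely
    forward-rotating (exp(+i w t)) pool contributes at +f only.
    """
    dt = np.diff(field.time_grid)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-12 * abs(dt[0])):
        raise WaveError("power spectrum requires a uniform time grid")
    n = len(field.time_grid)
    X = np.fft.fft(field.values, axis=1)
    power = np.mean(np.abs(X) ** 2, axis=0) / n**2
    freqs = np.fft.fftfreq(n, d=1.0 / field.sampling_rate)
    order = np.argsort(freqs)
    return PowerSpectrum(freqs[order], power[order])


def peak_locations(
    spectrum: PowerSpectrum, n_peaks: int
) -> list[tuple[float, float]]:
    """The ``n_peaks`` tallest local maxima, as (frequency, height), sorted
    by height descending.

    A bin is a local maximum if it strictly exceeds its left neighbour,
    is at least its right neighbour (so a tone split evenly between two
    bins still registers once), and carries nonzero power.  If fewer
    maxima exist than requested, the shorter list is returned with a
    warning.
    """
    p = spectrum.power
    idx = [
        i
        for i in range(1, len(p) - 1)
        if p[i] > p[i - 1] and p[i] >= p[i + 1] and p[i] > 0
    ]
    idx.sort(key=lambda i: p[i], reverse=True)
    if len(idx) < n_peaks:
        warnings.warn(
            f"requested {n_peaks} peaks but found {len(idx)} local maxima",
            stacklevel=2,
        )
    return [(float(spectrum.frequencies[i]), float(p[i])) for i in idx[:n_peaks]]


def signaling_peak(
    spectrum: PowerSpectrum, n_peaks: int = 2
) -> tuple[float, float]:
    """Lower-frequency member of the dominant peaks (the Src-inhibition peak)."""
    peaks = peak_locations(spectrum, n_peaks)
    if not peaks:
        raise WaveError("no spectral peaks found")
    return min(peaks, key=lambda fh: fh[0])
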