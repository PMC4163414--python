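"""Empirical mode decomposition and Hilbert spectral analysis.

A real signal x(t) is sifted into intrinsic mode functions (IMFs) g_i(t)
plus a residue r_N(t), so that x(t) = sum_i g_i(t) + r_N(t) holds exactly.
Each IMF admits a meaningful analytic signal: its Hilbert transform gives
an instantaneous amplitude G_i(t) and instantaneous frequency w_i(t), and
depositing G_i(t)^2 at (t, w_i(t)) builds the Hilbert spectrum H(w, t),
the time-frequency energy distribution that the band-energy features
integrate over.

Numerical conventions (the classical sifting literature leaves these open):

* envelopes are natural cubic splines through the local extrema, with two
  extrema mirror-reflected at each record end to curb end swings;
* a sift iteration stops on a Cauchy-type criterion
  sum((h_prev - h_new)^2) / sum(h_prev^2) < ``sd_stop`` (default 0.2),
  with a hard cap of ``max_sift`` iterations;
* decomposition stops when the residue has fewer than 2 maxima or minima
  (monotone-like) or ``max_imfs`` IMFs have been extracted;
* instantaneous frequency is the central-difference derivative of the
  unwrapped analytic phase; samples with non-physical IF (negative or
  above Nyquist) are masked out of the spectrum rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert as _hilbert

from ._envelope import envelope_mean

__all__ = [
    "IMFSet",
    "AnalyticTrace",
    "HilbertSpectrum",
    "sift_once",
    "emd",
    "analytic_signal",
    "hilbert_spectrum",
    "MonotoneResidueError",
]

#: spectrum frequency grid: 0.5 Hz bins spanning 0-128.5 Hz (257 bins)
FREQ_BIN_HZ = 0.5
FREQ_MAX_HZ = 128.5
N_FREQ_BINS = int(round(FREQ_MAX_HZ / FREQ_BIN_HZ))  # 257


class MonotoneResidueError(ValueError):
    """Raised by sift_once when the input has <2 maxima or <2 minima."""


@dataclass
class IMFSet:
    """Decomposition product: ordered IMFs plus the final residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_length: int

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for g in self.imfs:
            out += g
        return out


@dataclass
class AnalyticTrace:
    """Instantaneous amplitude, unwrapped phase and frequency of one IMF."""

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray  # Hz


@dataclass
class HilbertSpectrum:
    """Time-frequency energy distribution of one channel segment.

    ``values[f, t]`` is the amplitude magnitude at frequency bin f and
    sample t; energy accumulates additively, i.e. values = sqrt of the
    summed squared IMF amplitudes deposited in the bin, so that
    sum(values**2) equals the total retained squared amplitude.
    """

    values: np.ndarray  # (N_FREQ_BINS, n_samples)
    fs: float
    channel_id: str = ""
    freq_edges: np.ndarray = field(
        default_factory=lambda: np.arange(N_FREQ_BINS + 1) * FREQ_BIN_HZ
    )

    @property
    def energy(self) -> np.ndarray:
        return self.values**2

    def total_energy(self) -> float:
        return float(np.sum(self.values**2))


def sift_once(signal: np.ndarray) -> np.ndarray:
    """One sifting step: signal minus the mean of its spline envelopes.

    Raises :class:`MonotoneResidueError` when the signal has fewer than two
    maxima or two minima, signalling a monotone-like residue to the caller.
    """
    x = np.ascontiguousarray(signal, dtype=np.float64)
    mean_env, n_max, n_min = envelope_mean(x)
    if n_max < 2 or n_min < 2:
        raise MonotoneResidueError(
            f"monotone residue: {n_max} maxima, {n_min} minima"
        )
    return x - mean_env


def emd(
    signal: np.ndarray,
    max_imfs: int = 12,
    sd_stop: float = 0.2,
    max_sift: int = 100,
) -> IMFSet:
    """Decompose a real signal into IMFs and a residue.

    The reconstruction identity sum(imfs) + residue == signal holds to
    floating-point accuracy by construction, because the residue is updated
    by exact subtraction of each extracted IMF.
    """
    x = np.ascontiguousarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        h = residue.copy()
        mean_env, n_max, n_min = envelope_mean(h)
        if n_max < 2 or n_min < 2:
            break  # monotone-like residue: decomposition finished
        for _ in range(max_sift):
            h_new = h - mean_env
            denom = float(np.dot(h, h))
            sd = float(np.dot(mean_env, mean_env)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_stop:
                break
            mean_env, n_max, n_min = envelope_mean(h)
            if n_max < 2 or n_min < 2:
                break
        imfs.append(h)
        residue = residue - h
    return IMFSet(imfs=imfs, residue=residue, source_length=x.shape[0])


def analytic_signal(imf: np.ndarray, fs: float) -> AnalyticTrace:
    """Analytic amplitude, phase and instantaneous frequency of one IMF.

    IF is dθ/dt / 2π from the unwrapped phase via np.gradient (central
    differences in the interior, one-sided at the edges).
    """
    x = np.asarray(imf, dtype=np.float64)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for the phase derivative")
    z = _hilbert(x)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    inst_freq = np.gradient(phase) * fs / (2.0 * np.pi)
    return AnalyticTrace(amplitude=amplitude, phase=phase, inst_freq=inst_freq)


def hilbert_spectrum(
    imfset: IMFSet, fs: float, channel_id: str = ""
) -> HilbertSpectrum:
    """Build the Hilbert spectrum H(w, t) of a channel segment.

    Each IMF's squared instantaneous amplitude is deposited in the 0.5 Hz
    frequency bin holding its instantaneous frequency at every sample;
    samples whose IF falls outside [0, 128.5) Hz are masked out. Stored
    values are amplitudes (sqrt of accumulated energy), so the squared mass
    identity sum(values**2) == sum_i sum_t G_i(t)^2 holds over retained
    points.
    """
    n = imfset.source_length
    energy = np.zeros((N_FREQ_BINS, n))
    for g in imfset.imfs:
        tr = analytic_signal(g, fs)
        fbin = np.floor(tr.inst_freq / FREQ_BIN_HZ).astype(np.int64)
        ok = (tr.inst_freq >= 0.0) & (fbin < N_FREQ_BINS)
        t_idx = np.nonzero(ok)[0]
        np.add.at(energy, (fbin[t_idx], t_idx), tr.amplitude[t_idx] ** 2)
    return HilbertSpectrum(values=np.sqrt(energy), fs=fs, channel_id=channel_id)


def mean_instantaneous_frequency(imf: np.ndarray, fs: float) -> float:
    """Amplitude-weighted mean IF of an IMF (diagnostic / test helper)."""
    tr = analytic_signal(imf, fs)
    w = tr.amplitude[1:-1] ** 2
    f = tr.inst_freq[1:-1]
    tot = float(np.sum(w))
    return float(np.sum(w * f) / tot) if tot > 0 else 0.0
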