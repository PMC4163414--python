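"""Synthetic 6-channel iEEG with a controllable preictal gamma signature.

The generator emulates the statistical structure the prediction pipeline
exploits, not real iEEG morphology: each channel is a sum over the ten
clinical frequency bands of an amplitude-modulated sinusoid

    x_k(t) = sum_b A[state, k, b] * env_b(t) * sin(2 pi f_b t + phi_b)
             + pink noise,

where f_b is the band's centre frequency, env_b(t) a slowly varying
non-negative AM envelope (low-pass Gaussian noise, default 0.2 Hz
bandwidth), and the pink (1/f) noise stands in for the broadband
background.  In the preictal state the gamma-band amplitudes of the focal
channels are multiplied by ``gamma_boost`` (default 2), mirroring the
empirical pattern that focal-channel gamma energies carry the
discriminative information; ``gamma_boost = 1`` is the null generator
used as negative control.

Every record is reproducible from an explicit integer seed; patient-level
datasets spawn per-record child seeds from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_ROLES, EEGRecord

__all__ = ["SynthParams", "Split", "SynthPatient", "generate_record", "generate_patient"]

#: band carrier frequencies (Hz), the midpoints of the tiled band intervals
BAND_CENTERS = np.array([2.25, 6.0, 9.0, 11.5, 15.5, 24.5, 36.0, 46.0, 71.0, 109.0])

#: baseline per-band amplitudes (µV), a broadly 1/f-shaped iEEG-like profile
BASE_AMPLITUDES = np.array([30.0, 20.0, 12.0, 10.0, 8.0, 6.0, 4.0, 3.0, 2.0, 1.5])

GAMMA_BAND_IDX = [6, 7, 8, 9]  # gamma1..gamma4 in STANDARD_BANDS order


@dataclass
class SynthParams:
    """Generator configuration; amplitudes in µV, durations in minutes."""

    fs: float = 256.0
    n_channels: int = 6
    channel_roles: tuple[str, ...] = DEFAULT_ROLES
    base_amplitudes: np.ndarray = field(default_factory=lambda: BASE_AMPLITUDES.copy())
    gamma_boost: float = 2.0
    am_bandwidth_hz: float = 0.2
    am_depth: float = 0.3
    pink_noise_rms: float = 2.0
    preictal_min: float = 40.0
    interictal_mean_min: float = 58.58
    interictal_sd_min: float = 6.97

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.base_amplitudes) < 0):
            raise ValueError("band amplitudes must be non-negative")
        if self.gamma_boost < 1.0:
            raise ValueError("gamma_boost must be >= 1")

    def amplitude_table(self, state: str) -> np.ndarray:
        """(n_channels, n_bands) amplitude table for a state.

        Preictal boosts the gamma bands of the focal channels by
        ``gamma_boost``; everything else matches the interictal table.
        """
        if state not in ("interictal", "preictal"):
            raise ValueError(f"unknown state {state!r}")
        table = np.tile(self.base_amplitudes, (self.n_channels, 1))
        if state == "preictal":
            for k, role in enumerate(self.channel_roles[: self.n_channels]):
                if role == "focal":
                    table[k, GAMMA_BAND_IDX] *= self.gamma_boost
        return table


def _lowpass_noise(n: int, fs: float, bandwidth_hz: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [0, bandwidth] Hz.

    Synthesized on a coarse grid (8x the bandwidth) and linearly
    interpolated to the full rate — the envelope varies over seconds, so
    full-rate FFT synthesis would waste nearly all its bins.
    """
    fs_env = max(8.0 * bandwidth_hz, 1.0)
    n_env = max(int(np.ceil(n * fs_env / fs)) + 2, 16)
    freqs = np.fft.rfftfreq(n_env, 1.0 / fs_env)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    spec[freqs > bandwidth_hz] = 0.0
    coarse = np.fft.irfft(spec, n_env)
    sd = coarse.std()
    if sd > 0:
        coarse /= sd
    t_coarse = np.arange(n_env) / fs_env
    t_full = np.arange(n) / fs
    return np.interp(t_full, t_coarse, coarse)


def _pink_noise(n: int, fs: float, rng) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise (flat below 1 Hz to bound the DC end)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec *= shaping
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_record(
    state: str,
    duration_s: float,
    params: SynthParams,
    seed: int,
) -> EEGRecord:
    """One labelled record of AM band oscillations plus pink noise.

    The seizure onset of a preictal record is placed at the record end
    (the record covers the ``duration_s`` seconds leading up to onset).
    """
    if state not in ("interictal", "preictal"):
        raise ValueError(f"unknown state {state!r}")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * params.fs))
    t = np.arange(n) / params.fs
    table = params.amplitude_table(state)
    data = np.empty((params.n_channels, n))
    for k in range(params.n_channels):
        x = np.zeros(n)
        for b, fc in enumerate(BAND_CENTERS):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            env = 1.0 + params.am_depth * _lowpass_noise(
                n, params.fs, params.am_bandwidth_hz, rng
            )
            np.clip(env, 0.0, None, out=env)
            x += table[k, b] * env * np.sin(2.0 * np.pi * fc * t + phi)
        x += params.pink_noise_rms * _pink_noise(n, params.fs, rng)
        data[k] = x
    onsets = [duration_s] if state == "preictal" else []
    return EEGRecord(
        samples=data,
        fs=params.fs,
        channel_ids=tuple(f"ch{i + 1}" for i in range(params.n_channels)),
        channel_roles=tuple(params.channel_roles[: params.n_channels]),
        seizure_onsets=onsets,
    )


@dataclass
class Split:
    """One leave-one-seizure-out train/test partition."""

    test_seizure: int
    test_interictal: list[int]
    train_seizures: list[int]
    train_interictal: list[int]


@dataclass
class SynthPatient:
    """N preictal records (one per seizure) + M interictal files + splits."""

    preictal: list[EEGRecord]
    interictal: list[EEGRecord]
    splits: list[Split]
    params: SynthParams
    seed: int

    @property
    def n_seizures(self) -> int:
        return len(self.preictal)


def make_splits(n_seizures: int, m_interictal: int) -> list[Split]:
    """Leave-one-seizure-out partitions with round-robin interictal files.

    Test set k holds preictal record k plus interictal files k, k+N,
    k+2N, ...; all remaining files train.  No file appears on both sides
    of the same split.
    """
    if m_interictal < n_seizures:
        raise ValueError("need at least as many interictal files as seizures")
    splits = []
    for k in range(n_seizures):
        test_int = list(range(k, m_interictal, n_seizures))
        splits.append(
            Split(
                test_seizure=k,
                test_interictal=test_int,
                train_seizures=[i for i in range(n_seizures) if i != k],
                train_interictal=[i for i in range(m_interictal) if i not in test_int],
            )
        )
    return splits


def generate_patient(
    n_seizures: int,
    m_interictal: int,
    params: SynthParams | None = None,
    seed: int = 0,
) -> SynthPatient:
    """A full synthetic patient with leave-one-seizure-out splits.

    Preictal records last ``params.preictal_min`` minutes with the onset at
    the record end; interictal file durations are drawn from a normal
    distribution (mean 58.58 min, sd 6.97 min by default, truncated at 10
    min).  Requires n_seizures >= 2 and m_interictal >= n_seizures.
    """
    if params is None:
        params = SynthParams()
    if n_seizures < 2:
        raise ValueError("need at least 2 seizures for train/test splits")
    if m_interictal < n_seizures:
        raise ValueError("need at least as many interictal files as seizures")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(n_seizures + m_interictal + 1)]
    dur_rng = np.random.default_rng(child_seeds[-1])
    preictal = [
        generate_record("preictal", params.preictal_min * 60.0, params, child_seeds[i])
        for i in range(n_seizures)
    ]
    interictal = []
    for j in range(m_interictal):
        dur_min = max(
            10.0,
            dur_rng.normal(params.interictal_mean_min, params.interictal_sd_min),
        )
        interictal.append(
            generate_record(
                "interictal", dur_min * 60.0, params, child_seeds[n_seizures + j]
            )
        )
    return SynthPatient(
        preictal=preictal,
        interictal=interictal,
        splits=make_splits(n_seizures, m_interictal),
        params=params,
        seed=seed,
    )
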