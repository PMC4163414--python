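"""Band-energy and groupiness features from per-channel Hilbert spectra.

For each of the six channels k, the spectrum of a 30 s window is reduced
to 31 features: the marginal energy E_Tot^k, the energy E_j^k in ten
clinical frequency bands j (δ through four γ sub-bands), the relative
contributions E_j^k / E_Tot^k, and the groupiness factor GF_j^k — the
coefficient of variation (population std over mean) of the band's
instantaneous-energy time series, a measure of how clumped the band's
energy is in time.  Six channels give the 186-dimensional window
descriptor.

Band edges: the printed integer band labels (δ 0.5–3, θ 4–7, α1 8–9,
α2 10–12, β1 13–17, β2 18–30, γ 31–40/41–50/51–90/91–128 Hz) leave gaps
between the integer edges; instantaneous frequency is continuous, so the
bands are tiled half-open with no gaps: δ=[0.5,4), θ=[4,8), α1=[8,10),
α2=[10,13), β1=[13,18), β2=[18,31), γ1=[31,41), γ2=[41,51), γ3=[51,91),
γ4=[91,128.5).  Mass below 0.5 Hz counts toward E_Tot only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hht import FREQ_BIN_HZ, HilbertSpectrum, IMFSet, analytic_signal

__all__ = [
    "BandScheme",
    "STANDARD_BANDS",
    "BandEnergySeries",
    "FeatureVector",
    "band_energies",
    "band_energies_from_imfs",
    "groupiness_factor",
    "extract_features",
    "feature_names",
]


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping (name, f_low, f_high) frequency bands."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = None
        prev_low = -np.inf
        for name, lo, hi in self.bands:
            if hi <= lo:
                raise ValueError(f"band {name}: empty interval [{lo}, {hi})")
            if lo < prev_low:
                raise ValueError("bands must be ordered by f_low")
            if prev_high is not None and lo < prev_high:
                raise ValueError(f"band {name} overlaps its predecessor")
            prev_low, prev_high = lo, hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)


STANDARD_BANDS = BandScheme(
    bands=(
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha1", 8.0, 10.0),
        ("alpha2", 10.0, 13.0),
        ("beta1", 13.0, 18.0),
        ("beta2", 18.0, 31.0),
        ("gamma1", 31.0, 41.0),
        ("gamma2", 41.0, 51.0),
        ("gamma3", 51.0, 91.0),
        ("gamma4", 91.0, 128.5),
    )
)


@dataclass
class BandEnergySeries:
    """Instantaneous band energies of one channel window.

    series[j, t] = E_j(t), the squared spectral amplitude summed over the
    frequency bins of band j at sample t.  Totals integrate over time with
    Δt = one sample period; total_energy covers the whole spectrum,
    including mass outside every band, so sum(band_totals) <= total_energy.
    """

    series: np.ndarray  # (n_bands, n_samples)
    scheme: BandScheme
    dt: float

    @property
    def band_totals(self) -> np.ndarray:
        return self.series.sum(axis=1) * self.dt

    total_energy: float = 0.0


@dataclass
class FeatureVector:
    """186 named features of one 30 s window (6 channels x 31 features)."""

    values: np.ndarray
    names: list[str]
    segment_id: str = ""
    label: str | None = None

    def __len__(self) -> int:
        return len(self.values)


def band_energies(
    spectrum: HilbertSpectrum, scheme: BandScheme = STANDARD_BANDS
) -> BandEnergySeries:
    """Reduce a Hilbert spectrum to per-band instantaneous energies.

    Frequency bins are assigned to bands by their lower edge (bins are
    0.5 Hz wide and every band edge is a multiple of 0.5 Hz, so each bin
    lies wholly inside one band or outside all).
    """
    energy = spectrum.energy  # (n_bins, n_samples)
    lo_edges = spectrum.freq_edges[:-1]
    dt = 1.0 / spectrum.fs
    series = np.empty((len(scheme), energy.shape[1]))
    for j, (_, lo, hi) in enumerate(scheme.bands):
        rows = (lo_edges >= lo) & (lo_edges < hi)
        series[j] = energy[rows].sum(axis=0)
    return BandEnergySeries(
        series=series,
        scheme=scheme,
        dt=dt,
        total_energy=float(energy.sum()) * dt,
    )


def band_energies_from_imfs(
    imfset: IMFSet, fs: float, scheme: BandScheme = STANDARD_BANDS
) -> BandEnergySeries:
    """Band energies straight from IMF analytic traces (fast path).

    Mathematically identical to building the dense spectrum and calling
    :func:`band_energies` — each sample's squared amplitude lands in the
    band holding its 0.5 Hz IF bin — but without allocating the grid.
    """
    n = imfset.source_length
    nb = len(scheme)
    series = np.zeros((nb, n))
    total = np.zeros(n)
    # map 0.5 Hz bin index -> band index (or -1)
    edges_lo = np.array([b[1] for b in scheme.bands])
    edges_hi = np.array([b[2] for b in scheme.bands])
    n_bins = int(round(128.5 / FREQ_BIN_HZ))
    bin_lo = np.arange(n_bins) * FREQ_BIN_HZ
    bin_band = np.full(n_bins, -1, dtype=np.int64)
    for j in range(nb):
        bin_band[(bin_lo >= edges_lo[j]) & (bin_lo < edges_hi[j])] = j
    for g in imfset.imfs:
        tr = analytic_signal(g, fs)
        fbin = np.floor(tr.inst_freq / FREQ_BIN_HZ).astype(np.int64)
        ok = (tr.inst_freq >= 0.0) & (fbin < n_bins)
        e = np.where(ok, tr.amplitude**2, 0.0)
        total += e
        band_of_t = np.where(ok, bin_band[np.clip(fbin, 0, n_bins - 1)], -1)
        for j in range(nb):
            series[j] += np.where(band_of_t == j, e, 0.0)
    dt = 1.0 / fs
    return BandEnergySeries(
        series=series, scheme=scheme, dt=dt, total_energy=float(total.sum()) * dt
    )


def groupiness_factor(energy_series: np.ndarray) -> float:
    """Coefficient of variation (population std / mean) of E_j(t).

    Zero by convention when the mean is zero (band silent in the window).
    """
    e = np.asarray(energy_series, dtype=np.float64)
    mean = e.mean()
    if mean == 0.0:
        return 0.0
    return float(e.std() / mean)


def feature_names(
    scheme: BandScheme = STANDARD_BANDS, n_channels: int = 6
) -> list[str]:
    """Stable channel-major feature ordering: E_Tot, E_j, E_j/E_Tot, GF_j."""
    names: list[str] = []
    for k in range(1, n_channels + 1):
        names.append(f"ch{k}_etot")
        names += [f"ch{k}_E_{b}" for b in scheme.names]
        names += [f"ch{k}_ratio_{b}" for b in scheme.names]
        names += [f"ch{k}_GF_{b}" for b in scheme.names]
    return names


def features_from_band_energies(
    per_channel: list[BandEnergySeries],
    scheme: BandScheme = STANDARD_BANDS,
    segment_id: str = "",
    label: str | None = None,
) -> FeatureVector:
    """Assemble the per-window feature vector from per-channel band energies."""
    vals: list[float] = []
    for bes in per_channel:
        totals = bes.band_totals
        etot = bes.total_energy
        vals.append(etot)
        vals.extend(totals)
        if etot > 0:
            vals.extend(totals / etot)
        else:
            vals.extend(np.zeros(len(scheme)))
        vals.extend(groupiness_factor(bes.series[j]) for j in range(len(scheme)))
    return FeatureVector(
        values=np.asarray(vals),
        names=feature_names(scheme, n_channels=len(per_channel)),
        segment_id=segment_id,
        label=label,
    )


def extract_features(
    segment_spectra: list[HilbertSpectrum],
    scheme: BandScheme = STANDARD_BANDS,
    segment_id: str = "",
    label: str | None = None,
) -> FeatureVector:
    """31 features per channel from the 6 per-channel Hilbert spectra.

    Ordering is channel-major: for each channel, E_Tot, then the ten band
    energies δ→γ4, then the ten ratios, then the ten groupiness factors.
    """
    if len(segment_spectra) != 6:
        raise ValueError(f"expected 6 channel spectra, got {len(segment_spectra)}")
    return features_from_band_energies(
        [band_energies(sp, scheme) for sp in segment_spectra],
        scheme=scheme,
        segment_id=segment_id,
        label=label,
    )
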