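"""Reading, cleaning and windowing of multichannel intracranial EEG.

Input dialect: the ASCII export style used by invasive monitoring archives
(one whitespace-separated row per sample, one column per channel, in µV).
EDF is accepted as an alternative when mne is installed.  Records carry six
channels by convention: three focal (near the seizure onset zone) and three
extrafocal.

Cleaning order: epileptologist-annotated artifact intervals are excluded
first, then a 50 Hz power-line notch is applied; recordings sampled at
512 Hz are decimated to 256 Hz so every 30 s analysis window holds exactly
7680 samples.  Windows advance by 15 s (50% overlap) and any window that
intersects an artifact interval is dropped whole — excising samples would
splice discontinuities into the signal and corrupt the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecord",
    "Segment",
    "read_ascii_record",
    "write_ascii_record",
    "read_edf_record",
    "read_artifact_file",
    "remove_artifacts",
    "notch_filter",
    "resample_to_256",
    "segment",
]

DEFAULT_ROLES = ("focal", "focal", "focal", "extrafocal", "extrafocal", "extrafocal")


@dataclass
class EEGRecord:
    """Multichannel iEEG with annotations.

    samples: (n_channels, n_samples) float array in µV.
    artifacts: half-open [t0, t1) intervals in seconds from record start.
    seizure_onsets: onset times in seconds, strictly increasing.
    """

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    channel_roles: tuple[str, ...]
    start_time: float = 0.0
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    seizure_onsets: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match sample rows")
        if len(self.channel_roles) != self.samples.shape[0]:
            raise ValueError("channel_roles length must match sample rows")
        dur = self.duration
        for t0, t1 in self.artifacts:
            if t1 < t0:
                raise ValueError(f"inverted artifact interval [{t0}, {t1})")
            if t0 < 0 or t0 > dur:
                raise ValueError(f"artifact interval [{t0}, {t1}) outside record span")
        if any(b <= a for a, b in zip(self.seizure_onsets, self.seizure_onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def focal_channels(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == "focal"]


@dataclass
class Segment:
    """One artifact-free analysis window (all channels)."""

    window_data: np.ndarray  # (n_channels, L)
    t_start: float  # seconds from record start
    fs: float
    label: str | None = None  # "preictal" | "interictal" | None

    @property
    def L(self) -> int:
        return self.window_data.shape[1]


def read_ascii_record(
    path,
    fs: float = 256.0,
    channel_roles: tuple[str, ...] = DEFAULT_ROLES,
    n_channels: int = 6,
    artifacts: list[tuple[float, float]] | None = None,
    seizure_onsets: list[float] | None = None,
) -> EEGRecord:
    """Parse a whitespace-separated ASCII sample matrix into an EEGRecord.

    One row per sample, ``n_channels`` numeric columns.  A malformed row
    (non-numeric token or wrong column count) raises ValueError naming the
    1-based line number.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != n_channels:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_channels} columns, "
                    f"got {len(toks)}"
                )
            try:
                rows.append([float(t) for t in toks])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from None
    data = np.asarray(rows, dtype=np.float64).T
    if data.size == 0:
        data = data.reshape(n_channels, 0)
    ids = tuple(f"ch{i + 1}" for i in range(n_channels))
    return EEGRecord(
        samples=data,
        fs=fs,
        channel_ids=ids,
        channel_roles=tuple(channel_roles),
        artifacts=list(artifacts or []),
        seizure_onsets=list(seizure_onsets or []),
    )


def write_ascii_record(record: EEGRecord, path) -> None:
    """Write a record in the same ASCII matrix dialect read_ascii_record reads."""
    np.savetxt(path, record.samples.T, fmt="%.6f")


def read_edf_record(
    path,
    channel_roles: tuple[str, ...] = DEFAULT_ROLES,
    artifacts: list[tuple[float, float]] | None = None,
    seizure_onsets: list[float] | None = None,
) -> EEGRecord:
    """Read an EDF file (requires mne); channel order is file order."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    return EEGRecord(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_ids=tuple(raw.ch_names),
        channel_roles=tuple(channel_roles)[: data.shape[0]],
        artifacts=list(artifacts or []),
        seizure_onsets=list(seizure_onsets or []),
    )


def read_artifact_file(path) -> list[tuple[float, float]]:
    """Parse artifact annotations: one "t_start t_end" (seconds) per line."""
    out: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            if len(toks) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 't0 t1'")
            t0, t1 = float(toks[0]), float(toks[1])
            out.append((t0, t1))
    return out


def remove_artifacts(record: EEGRecord) -> list[tuple[float, float]]:
    """Usable time ranges: the record span minus all artifact intervals.

    Returns a sorted list of disjoint half-open [t0, t1) second intervals.
    """
    dur = record.duration
    ivs = sorted((max(0.0, a), min(dur, b)) for a, b in record.artifacts)
    for a, b in ivs:
        if b < a:
            raise ValueError(f"inverted artifact interval [{a}, {b})")
    usable: list[tuple[float, float]] = []
    cursor = 0.0
    for a, b in ivs:
        if a > cursor:
            usable.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < dur:
        usable.append((cursor, dur))
    return usable


def notch_filter(record: EEGRecord, f0: float = 50.0, q: float = 30.0) -> EEGRecord:
    """Remove power-line interference with a zero-phase IIR notch.

    Second-order notch (quality factor ``q``) applied forward-backward so
    the passband phase is untouched and the filter is idempotent there.
    """
    if record.fs <= 2 * f0:
        raise ValueError(f"fs={record.fs} must exceed 2*f0={2 * f0} for the notch")
    b, a = sps.iirnotch(f0, q, fs=record.fs)
    filtered = sps.filtfilt(b, a, record.samples, axis=1)
    return replace(record, samples=filtered)


def resample_to_256(record: EEGRecord) -> EEGRecord:
    """Bring a record to the common 256 Hz rate.

    256 Hz input is returned unchanged; 512 Hz is decimated by 2 with
    scipy's zero-phase anti-alias filter.  Other rates are rejected.
    """
    if record.fs == 256:
        return record
    if record.fs == 512:
        dec = sps.decimate(record.samples, 2, axis=1, zero_phase=True)
        arts = list(record.artifacts)
        onsets = list(record.seizure_onsets)
        return replace(record, samples=dec, fs=256.0, artifacts=arts, seizure_onsets=onsets)
    raise ValueError(f"unsupported sampling rate {record.fs}; expected 256 or 512")


def _intersects(t0: float, t1: float, intervals) -> bool:
    return any(a < t1 and t0 < b for a, b in intervals)


def segment(
    record: EEGRecord, win_s: float = 30.0, overlap: float = 0.5
) -> list[Segment]:
    """Slide a win_s window with the given overlap; drop artifact windows.

    Windows are half-open [t, t + win_s) anchored at the record start and
    advance by win_s * (1 - overlap) seconds (15 s at the defaults).  A
    record shorter than one window yields an empty list.  Any window that
    intersects an annotated artifact interval is dropped.
    """
    step = win_s * (1.0 - overlap)
    L = int(round(win_s * record.fs))
    out: list[Segment] = []
    t = 0.0
    k = 0
    while True:
        t = k * step
        i0 = int(round(t * record.fs))
        if i0 + L > record.n_samples:
            break
        if not _intersects(t, t + win_s, record.artifacts):
            out.append(
                Segment(
                    window_data=record.samples[:, i0 : i0 + L],
                    t_start=t,
                    fs=record.fs,
                )
            )
        k += 1
    return out
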