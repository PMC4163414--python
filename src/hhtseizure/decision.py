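"""Postprocessing of per-window probabilities into decisions and alarms.

The classifier emits P(preictal) every 15 s; raising an alarm at that
cadence would be useless to a patient, so probabilities are averaged over
consecutive non-overlapping 5-minute decision blocks anchored at the
record start.  A block is declared preictal when its mean probability is
>= the operating threshold, and each preictal block's start time is a raw
alarm.  Raw alarms within SPH + SOP (default 40 min) of the first alarm
of a cluster merge into that cluster; clusters are the countable alarm
events used for false-positive bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecisionSeries",
    "AlarmList",
    "aggregate_blocks",
    "threshold_blocks",
    "alarms_from_decisions",
]


@dataclass
class DecisionSeries:
    """Block times (s), mean probabilities, threshold, and decisions."""

    block_starts: np.ndarray  # seconds
    block_means: np.ndarray
    threshold: float
    decisions: np.ndarray  # bool, True = preictal

    def __len__(self) -> int:
        return len(self.block_starts)


@dataclass
class AlarmList:
    """Raw alarm times and their SPH+SOP clusters."""

    alarm_times: np.ndarray  # seconds, strictly increasing (raw alarms)
    clusters: list[list[float]] = field(default_factory=list)

    @property
    def n_raw(self) -> int:
        return len(self.alarm_times)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def cluster_starts(self) -> list[float]:
        return [c[0] for c in self.clusters]


def aggregate_blocks(
    probs: np.ndarray,
    window_times: np.ndarray | None = None,
    block_s: float = 300.0,
    window_step_s: float = 15.0,
):
    """Mean probability per consecutive 5-minute block.

    ``window_times`` are the window start times in seconds (defaults to a
    gap-free 15 s cadence from zero).  Artifact gaps are allowed: a block
    averages whatever windows fall in it; a block with no windows emits no
    decision.  Returns (block_starts, block_means).
    """
    probs = np.asarray(probs, dtype=np.float64)
    if window_times is None:
        window_times = np.arange(len(probs)) * window_step_s
    window_times = np.asarray(window_times, dtype=np.float64)
    if len(window_times) != len(probs):
        raise ValueError("window_times and probs must have equal length")
    if len(probs) == 0:
        return np.empty(0), np.empty(0)
    blk = np.floor(window_times / block_s).astype(np.int64)
    starts, means = [], []
    for b in np.unique(blk):
        sel = blk == b
        starts.append(b * block_s)
        means.append(probs[sel].mean())
    return np.asarray(starts), np.asarray(means)


def threshold_blocks(
    block_starts: np.ndarray, block_means: np.ndarray, thr: float
) -> DecisionSeries:
    """Declare each block preictal iff its mean probability >= thr."""
    if not 0.0 <= thr <= 1.0:
        raise ValueError(f"threshold {thr} outside [0, 1]")
    means = np.asarray(block_means, dtype=np.float64)
    return DecisionSeries(
        block_starts=np.asarray(block_starts, dtype=np.float64),
        block_means=means,
        threshold=thr,
        decisions=means >= thr,
    )


def alarms_from_decisions(
    decisions: DecisionSeries, sph_min: float = 5.0, sop_min: float = 35.0
) -> AlarmList:
    """Raw alarms (preictal block starts) clustered over SPH + SOP.

    A raw alarm joins the current cluster when it falls within
    (sph_min + sop_min) minutes of the cluster's first alarm; otherwise it
    starts a new cluster.
    """
    horizon_s = (sph_min + sop_min) * 60.0
    times = decisions.block_starts[decisions.decisions]
    clusters: list[list[float]] = []
    for t in times:
        if clusters and t - clusters[-1][0] <= horizon_s:
            clusters[-1].append(float(t))
        else:
            clusters.append([float(t)])
    return AlarmList(alarm_times=np.asarray(times, dtype=np.float64), clusters=clusters)
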