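"""Patient-level prediction model and results (the orchestration surface).

`SeizurePredictor` is built from one patient's labelled records plus a
`RunConfig`; `fit()` runs the leave-one-seizure-out protocol — for every
split it selects features (CFS) and estimates the Bayesian network on the
training records only, then scores the held-out preictal record and its
assigned interictal files — and returns a `SeizurePredictorResults`
carrying the per-window probabilities, per-split selections and trained
networks.  Evaluation at an operating threshold, the threshold-sweep
curve, the text summary and plotting hang off the results object.

Preprocessing inside fit(): artifact exclusion, 50 Hz notch, decimation of
512 Hz records to 256 Hz, 30 s windows with 50% overlap; each window is
reduced to the 186 Hilbert-spectrum band-energy features.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes, cfs
from .decision import aggregate_blocks, alarms_from_decisions, threshold_blocks
from .evaluation import (
    EvaluationReport,
    aggregate_report,
    score_interictal,
    score_preictal,
    sensitivity_fph_curve,
)
from .features import STANDARD_BANDS, band_energies_from_imfs, feature_names, \
    features_from_band_energies
from .hht import emd
from .io import EEGRecord, notch_filter, resample_to_256, segment
from .synthetic import SynthPatient

__all__ = ["RunConfig", "SeizurePredictor", "SeizurePredictorResults",
           "run_patient", "run_threshold_sweep", "extract_record_features"]


@dataclass
class RunConfig:
    """End-to-end workflow configuration."""

    win_s: float = 30.0
    overlap: float = 0.5
    block_s: float = 300.0
    sph_min: float = 5.0
    sop_min: float = 35.0
    threshold: float = 0.25
    structure: str = "naive"  # or "k2-1parent"
    feature_selection: bool = True
    notch_hz: float | None = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sph_min <= 0 or self.sop_min <= 0:
            raise ValueError("SPH and SOP must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold outside [0, 1]")


def extract_record_features(record: EEGRecord, config: RunConfig,
                            label: str | None = None):
    """Preprocess one record and compute per-window feature rows.

    Returns (feature_matrix, window_start_times).  Windows overlapping
    artifact annotations are dropped before decomposition.
    """
    rec = resample_to_256(record)
    if config.notch_hz is not None:
        rec = notch_filter(rec, f0=config.notch_hz)
    segs = segment(rec, win_s=config.win_s, overlap=config.overlap)
    rows, times = [], []
    for sg in segs:
        per_channel = [
            band_energies_from_imfs(emd(sg.window_data[k]), sg.fs, STANDARD_BANDS)
            for k in range(sg.window_data.shape[0])
        ]
        fv = features_from_band_energies(per_channel, STANDARD_BANDS, label=label)
        rows.append(fv.values)
        times.append(sg.t_start)
    X = np.asarray(rows) if rows else np.empty((0, 31 * record.n_channels))
    return X, np.asarray(times)


@dataclass
class _RecordEval:
    """Per-window classifier output for one held-out record."""

    kind: str  # "preictal" | "interictal"
    window_times: np.ndarray
    probs: np.ndarray
    duration_s: float
    onset_s: float | None


@dataclass
class SplitResult:
    split_index: int
    selected_features: list[str]
    merit: float
    model: bayes.BayesNetModel
    records: list[_RecordEval]
    train_hash: str


class SeizurePredictor:
    """Patient-specific seizure prediction model.

    Parameters
    ----------
    preictal, interictal : lists of EEGRecord (preictal records carry the
        seizure onset as their last annotation).
    splits : leave-one-seizure-out partitions (see synthetic.make_splits).
    config : RunConfig.
    """

    def __init__(self, preictal, interictal, splits, config: RunConfig | None = None):
        self.preictal = list(preictal)
        self.interictal = list(interictal)
        self.splits = list(splits)
        self.config = config or RunConfig()
        for sp in self.splits:
            leak_pre = set(sp.train_seizures) & {sp.test_seizure}
            leak_int = set(sp.train_interictal) & set(sp.test_interictal)
            if leak_pre or leak_int:
                raise ValueError(
                    f"train/test leakage in split {sp.test_seizure}: "
                    f"preictal {sorted(leak_pre)}, interictal {sorted(leak_int)}"
                )

    @classmethod
    def from_synthetic(cls, patient: SynthPatient, config: RunConfig | None = None):
        return cls(patient.preictal, patient.interictal, patient.splits, config)

    def _extract_all(self, progress: bool = False):
        names = feature_names(STANDARD_BANDS, n_channels=self.preictal[0].n_channels)
        pre_feats, int_feats = [], []
        for rec in self.preictal:
            pre_feats.append(extract_record_features(rec, self.config, "preictal"))
        for rec in self.interictal:
            int_feats.append(extract_record_features(rec, self.config, "interictal"))
        return names, pre_feats, int_feats

    def fit(self) -> "SeizurePredictorResults":
        """Run feature extraction, per-split selection/training and scoring."""
        cfg = self.config
        names, pre_feats, int_feats = self._extract_all()
        split_results: list[SplitResult] = []
        for si, sp in enumerate(self.splits):
            Xtr = np.vstack(
                [pre_feats[i][0] for i in sp.train_seizures]
                + [int_feats[j][0] for j in sp.train_interictal]
            )
            ytr = np.array(
                ["preictal"] * sum(len(pre_feats[i][0]) for i in sp.train_seizures)
                + ["interictal"] * sum(len(int_feats[j][0]) for j in sp.train_interictal)
            )
            train_hash = hashlib.sha256(
                np.ascontiguousarray(Xtr).tobytes()
            ).hexdigest()[:16]
            if cfg.feature_selection:
                sel = cfs.best_first_select(Xtr, ytr, feature_names=names)
                idx = sel.selected_idx or list(range(Xtr.shape[1]))
                sel_names, merit = sel.selected, sel.merit
            else:
                idx = list(range(Xtr.shape[1]))
                sel_names, merit = list(names), float("nan")
            model = bayes.fit(
                Xtr[:, idx], ytr, structure=cfg.structure,
                attr_names=[names[i] for i in idx],
            )
            records: list[_RecordEval] = []
            pre_rec = self.preictal[sp.test_seizure]
            X, times = pre_feats[sp.test_seizure]
            records.append(
                _RecordEval(
                    kind="preictal",
                    window_times=times,
                    probs=bayes.predict_proba(model, X[:, idx]),
                    duration_s=pre_rec.duration,
                    onset_s=pre_rec.seizure_onsets[-1]
                    if pre_rec.seizure_onsets
                    else pre_rec.duration,
                )
            )
            for j in sp.test_interictal:
                X, times = int_feats[j]
                records.append(
                    _RecordEval(
                        kind="interictal",
                        window_times=times,
                        probs=bayes.predict_proba(model, X[:, idx]),
                        duration_s=self.interictal[j].duration,
                        onset_s=None,
                    )
                )
            split_results.append(
                SplitResult(
                    split_index=si,
                    selected_features=sel_names,
                    merit=merit,
                    model=model,
                    records=records,
                    train_hash=train_hash,
                )
            )
        return SeizurePredictorResults(self, split_results)


class SeizurePredictorResults:
    """Fitted per-split models, held-out probabilities, and evaluation."""

    def __init__(self, model: SeizurePredictor, split_results: list[SplitResult]):
        self.model = model
        self.split_results = split_results

    @property
    def mean_selected_count(self) -> float:
        return float(
            np.mean([len(sr.selected_features) for sr in self.split_results])
        )

    def _score_at(self, threshold: float, patient_id: str = "patient"):
        cfg = self.model.config
        pre_scores, int_scores = [], []
        for sr in self.split_results:
            for rec in sr.records:
                starts, means = aggregate_blocks(
                    rec.probs, rec.window_times, block_s=cfg.block_s
                )
                ds = threshold_blocks(starts, means, threshold)
                alarms = alarms_from_decisions(ds, cfg.sph_min, cfg.sop_min)
                if rec.kind == "preictal":
                    pre_scores.append(
                        score_preictal(alarms, rec.onset_s, cfg.sph_min, cfg.sop_min)
                    )
                else:
                    int_scores.append(
                        score_interictal(
                            alarms, rec.duration_s, cfg.sph_min, cfg.sop_min
                        )
                    )
        return {patient_id: (pre_scores, int_scores)}

    def evaluate(self, threshold: float | None = None,
                 patient_id: str = "patient") -> EvaluationReport:
        """Score all held-out records at a threshold and build the report."""
        thr = self.model.config.threshold if threshold is None else threshold
        cfg = self.model.config
        return aggregate_report(
            self._score_at(thr, patient_id), cfg.sph_min, cfg.sop_min
        )

    def threshold_sweep(self, thresholds) -> pd.DataFrame:
        """Pooled (FPs/h, sensitivity) operating points over a threshold grid."""
        return sensitivity_fph_curve(lambda t: self.evaluate(t), thresholds)

    def summary(self, threshold: float | None = None) -> str:
        rep = self.evaluate(threshold)
        lines = [
            "SeizurePredictor results",
            f"  splits: {len(self.split_results)}  "
            f"structure: {self.model.config.structure}  "
            f"feature selection: {self.model.config.feature_selection}",
            f"  mean selected features per split: {self.mean_selected_count:.2f}",
            rep.summary(),
        ]
        return "\n".join(lines)

    def plot_decisions(self, split: int = 0, record: int = 0, threshold=None, ax=None):
        """Per-window probabilities and 5-min block means of one test record."""
        import matplotlib.pyplot as plt

        thr = self.model.config.threshold if threshold is None else threshold
        rec = self.split_results[split].records[record]
        starts, means = aggregate_blocks(
            rec.probs, rec.window_times, block_s=self.model.config.block_s
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(rec.window_times / 60.0, rec.probs, ".", ms=2, label="P(preictal)/15 s")
        ax.step(starts / 60.0, means, where="post", lw=2, label="5-min mean")
        ax.axhline(thr, color="r", ls="--", label=f"threshold {thr}")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("probability")
        ax.set_title(f"split {split}, {rec.kind} record")
        ax.legend()
        return ax


def run_patient(config: RunConfig, patient: SynthPatient,
                patient_id: str = "patient") -> EvaluationReport:
    """Fit the leave-one-seizure-out model and evaluate at config.threshold."""
    res = SeizurePredictor.from_synthetic(patient, config).fit()
    return res.evaluate(config.threshold, patient_id=patient_id)


def run_threshold_sweep(config: RunConfig, patient: SynthPatient,
                        thresholds) -> pd.DataFrame:
    """Fit once, then sweep the decision threshold over a grid."""
    if len(list(thresholds)) < 2:
        raise ValueError("need a grid of at least 2 thresholds")
    res = SeizurePredictor.from_synthetic(patient, config).fit()
    return res.threshold_sweep(thresholds)
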