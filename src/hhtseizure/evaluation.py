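"""SPH/SOP scoring, performance measures, and chance-predictor validation.

An alarm at time a predicts a seizure correctly when the onset falls in
[a + SPH, a + SPH + SOP]: the patient gets at least SPH (5 min) to prepare
and waits at most SPH + SOP (40 min).  Sensitivity is the fraction of
seizures so predicted; detection latency is onset minus the earliest
qualifying alarm.  On seizure-free records, false positives are counted as
alarm clusters and time in warning as the union of the [a, a + SPH + SOP)
intervals over raw alarms, clipped to the record.

Statistical validation compares the system with an unspecific Poisson
chance predictor whose alarms have rate lambda_w chosen so that it spends
the same proportion of time rho_w in warning:

    lambda_w = -ln(1 - rho_w) / (SPH + SOP)
    Snc      = 1 - exp(-lambda_w (SPH + SOP) + (1 - e^{-lambda_w SPH}))

(the Snc expression is kept exactly in this printed composition — it is
what reproduces the published per-patient P values), and the one-sided
significance of predicting n of N seizures is the binomial tail

    P = 1 - sum_{k=0}^{n-1} C(N, k) Snc^k (1 - Snc)^{N-k}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, exp, log

import numpy as np
import pandas as pd

from .decision import AlarmList

__all__ = [
    "PreictalScore",
    "InterictalScore",
    "EvaluationReport",
    "score_preictal",
    "score_interictal",
    "chance_sensitivity",
    "chance_p_value",
    "aggregate_report",
    "sensitivity_fph_curve",
]

SPH_MIN = 5.0
SOP_MIN = 35.0


@dataclass
class PreictalScore:
    predicted: bool
    latency_min: float | None  # onset - earliest qualifying alarm, minutes


@dataclass
class InterictalScore:
    fp_count: int
    warned_time_min: float
    duration_min: float


def score_preictal(
    alarms: AlarmList,
    onset_s: float | None,
    sph_min: float = SPH_MIN,
    sop_min: float = SOP_MIN,
) -> PreictalScore:
    """TP/FN outcome of one preictal record.

    True positive iff some raw alarm a satisfies
    onset in [a + SPH, a + SPH + SOP]; the latency reported is from the
    earliest qualifying alarm.  Alarms closer to onset than SPH do not
    qualify (the seizure falls inside the preparation horizon).
    """
    if onset_s is None:
        raise ValueError("preictal record requires a seizure onset time")
    lo, hi = sph_min * 60.0, (sph_min + sop_min) * 60.0
    for a in np.sort(np.asarray(alarms.alarm_times)):
        lead = onset_s - a
        if lo <= lead <= hi:
            return PreictalScore(predicted=True, latency_min=lead / 60.0)
    return PreictalScore(predicted=False, latency_min=None)


def score_interictal(
    alarms: AlarmList,
    duration_s: float,
    sph_min: float = SPH_MIN,
    sop_min: float = SOP_MIN,
) -> InterictalScore:
    """False positives and time in warning on a seizure-free record.

    FP count is the number of alarm clusters; warned time is the union of
    [a, a + SPH + SOP) over raw alarms, clipped to the record span.
    """
    horizon_s = (sph_min + sop_min) * 60.0
    intervals = [
        (float(a), min(float(a) + horizon_s, duration_s))
        for a in np.sort(np.asarray(alarms.alarm_times))
    ]
    warned = 0.0
    cursor = -np.inf
    for a, b in intervals:
        if a > cursor:
            warned += b - a
            cursor = b
        elif b > cursor:
            warned += b - cursor
            cursor = b
    return InterictalScore(
        fp_count=alarms.n_clusters,
        warned_time_min=warned / 60.0,
        duration_min=duration_s / 60.0,
    )


def chance_sensitivity(
    rho_w: float, sph_min: float = SPH_MIN, sop_min: float = SOP_MIN
) -> float:
    """Sensitivity Snc of the Poisson chance predictor.

    rho_w is the proportion of time spent in warning, in [0, 1).
    """
    if not 0.0 <= rho_w < 1.0:
        raise ValueError(f"rho_w={rho_w} outside [0, 1)")
    if rho_w == 0.0:
        return 0.0
    horizon = sph_min + sop_min
    lam = -log(1.0 - rho_w) / horizon
    return 1.0 - exp(-lam * horizon + (1.0 - exp(-lam * sph_min)))


def chance_p_value(n: int, N: int, snc: float) -> float:
    """One-sided binomial tail P(X >= n), X ~ Binomial(N, Snc).

    n = 0 gives P = 1 (empty sum).  Matches brute-force enumeration over
    all 2^N alarm/seizure outcome sequences.
    """
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0.0 <= snc < 1.0:
        raise ValueError(f"Snc={snc} outside [0, 1)")
    return 1.0 - sum(
        comb(N, k) * snc**k * (1.0 - snc) ** (N - k) for k in range(n)
    )


@dataclass
class EvaluationReport:
    """Per-patient rows plus pooled summary in the standard column layout."""

    per_patient: pd.DataFrame  # columns: patient, n_seizures, interictal_h,
    #                            sens_pct, det_lat_min, fps_per_h, fp_pct, p_value
    pooled: dict = field(default_factory=dict)

    COLUMNS = [
        "patient",
        "n_seizures",
        "interictal_h",
        "sens_pct",
        "det_lat_min",
        "fps_per_h",
        "fp_pct",
        "p_value",
    ]

    def to_csv(self, path) -> None:
        self.per_patient.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            "Seizure prediction evaluation (SPH=5 min, SOP=35 min)",
            self.per_patient.to_string(index=False),
            "",
            "Pooled: sens={sens_pct:.2f}%  lat={det_lat_min}  "
            "FPs/h={fps_per_h:.3f}  FP%={fp_pct:.3f}".format(
                sens_pct=self.pooled["sens_pct"],
                det_lat_min=(
                    f"{self.pooled['det_lat_min']:.2f} min"
                    if self.pooled["det_lat_min"] is not None
                    else "n/a"
                ),
                fps_per_h=self.pooled["fps_per_h"],
                fp_pct=self.pooled["fp_pct"],
            ),
        ]
        return "\n".join(lines)


def _patient_row(
    patient: str,
    preictal_scores: list[PreictalScore],
    interictal_scores: list[InterictalScore],
    sph_min: float,
    sop_min: float,
) -> dict:
    N = len(preictal_scores)
    n = sum(s.predicted for s in preictal_scores)
    lats = [s.latency_min for s in preictal_scores if s.predicted]
    inter_min = sum(s.duration_min for s in interictal_scores)
    fp = sum(s.fp_count for s in interictal_scores)
    warned = sum(s.warned_time_min for s in interictal_scores)
    fp_pct = 100.0 * warned / inter_min if inter_min > 0 else 0.0
    rho = min(fp_pct / 100.0, 1.0 - 1e-12)
    snc = chance_sensitivity(rho, sph_min, sop_min)
    return {
        "patient": patient,
        "n_seizures": N,
        "interictal_h": inter_min / 60.0,
        "sens_pct": 100.0 * n / N if N else np.nan,
        "det_lat_min": float(np.mean(lats)) if lats else np.nan,
        "fps_per_h": fp / (inter_min / 60.0) if inter_min > 0 else np.nan,
        "fp_pct": fp_pct,
        "p_value": chance_p_value(n, N, snc) if N else np.nan,
        "_n": n,
        "_fp": fp,
        "_inter_min": inter_min,
        "_lats": lats,
    }


def aggregate_report(
    per_patient_scores: dict[str, tuple[list[PreictalScore], list[InterictalScore]]],
    sph_min: float = SPH_MIN,
    sop_min: float = SOP_MIN,
) -> EvaluationReport:
    """Assemble the per-patient table and pooled measures.

    Pooled sensitivity is seizure-weighted (100 * sum n / sum N); FPs/h
    pools false positives over total interictal hours; latency averages
    over all true positives.
    """
    rows = []
    for patient, (pre, inter) in per_patient_scores.items():
        if not pre:
            raise ValueError(f"patient {patient}: no scored preictal records")
        rows.append(_patient_row(patient, pre, inter, sph_min, sop_min))
    all_lats = [v for r in rows for v in r["_lats"]]
    tot_N = sum(r["n_seizures"] for r in rows)
    tot_n = sum(r["_n"] for r in rows)
    tot_inter_min = sum(r["_inter_min"] for r in rows)
    tot_warn = sum(r["fp_pct"] / 100.0 * r["_inter_min"] for r in rows)
    pooled = {
        "sens_pct": 100.0 * tot_n / tot_N if tot_N else np.nan,
        "det_lat_min": float(np.mean(all_lats)) if all_lats else None,
        "fps_per_h": (
            sum(r["_fp"] for r in rows) / (tot_inter_min / 60.0)
            if tot_inter_min > 0
            else np.nan
        ),
        "fp_pct": 100.0 * tot_warn / tot_inter_min if tot_inter_min > 0 else 0.0,
        "n_predicted": tot_n,
        "n_seizures": tot_N,
    }
    df = pd.DataFrame(rows)[EvaluationReport.COLUMNS]
    return EvaluationReport(per_patient=df, pooled=pooled)


def sensitivity_fph_curve(
    evaluate_at,
    thresholds,
):
    """Sweep the decision threshold and collect (threshold, FPs/h, sens%).

    ``evaluate_at(thr)`` must return an EvaluationReport; the curve is the
    pooled operating point per threshold.  Returns a DataFrame with columns
    threshold, fps_per_h, sens_pct.
    """
    pts = []
    for thr in thresholds:
        rep = evaluate_at(thr)
        pts.append(
            {
                "threshold": thr,
                "fps_per_h": rep.pooled["fps_per_h"],
                "sens_pct": rep.pooled["sens_pct"],
            }
        )
    return pd.DataFrame(pts)
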