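"""SPH/SOP scoring and the Poisson chance predictor."""

import itertools

import numpy as np
import pytest

from hhtseizure.decision import AlarmList
from hhtseizure.evaluation import (
    aggregate_report,
    chance_p_value,
    chance_sensitivity,
    InterictalScore,
    PreictalScore,
    score_interictal,
    score_preictal,
    sensitivity_fph_curve,
)


def _alarms(minutes):
    times = np.asarray(sorted(minutes), dtype=float) * 60.0
    clusters, horizon = [], 40.0 * 60
    for t in times:
        if clusters and t - clusters[-1][0] <= horizon:
            clusters[-1].append(float(t))
        else:
            clusters.append([float(t)])
    return AlarmList(alarm_times=times, clusters=clusters)


class TestScorePreictal:
    def test_alarm_36min_before_onset_is_tp(self):
        s = score_preictal(_alarms([4.0]), onset_s=40.0 * 60)
        assert s.predicted and s.latency_min == pytest.approx(36.0)

    def test_alarm_inside_sph_is_fn(self):
        s = score_preictal(_alarms([37.0]), onset_s=40.0 * 60)
        assert not s.predicted

    def test_no_alarms_is_fn(self):
        s = score_preictal(_alarms([]), onset_s=2400.0)
        assert not s.predicted and s.latency_min is None

    def test_earliest_qualifying_alarm_sets_latency(self):
        s = score_preictal(_alarms([5.0, 20.0]), onset_s=40.0 * 60)
        assert s.latency_min == pytest.approx(35.0)

    def test_missing_onset_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            score_preictal(_alarms([1.0]), onset_s=None)


class TestScoreInterictal:
    def test_no_alarms(self):
        s = score_interictal(_alarms([]), duration_s=3600.0)
        assert (s.fp_count, s.warned_time_min) == (0, 0.0)

    def test_single_alarm_warns_40min(self):
        s = score_interictal(_alarms([10.0]), duration_s=7200.0)
        assert s.fp_count == 1
        assert s.warned_time_min == pytest.approx(40.0)

    def test_overlapping_alarms_union(self):
        # raw alarms at 0, 35, 70 min: clusters {0,35},{70}; union [0,110)
        s = score_interictal(_alarms([0.0, 35.0, 70.0]), duration_s=4 * 3600.0)
        assert s.fp_count == 2
        assert s.warned_time_min == pytest.approx(110.0)

    def test_warning_clipped_to_record(self):
        s = score_interictal(_alarms([50.0]), duration_s=3600.0)
        assert s.warned_time_min == pytest.approx(10.0)

    def test_warned_time_bounded(self, rng):
        for _ in range(20):
            mins = sorted(rng.uniform(0, 120, rng.integers(0, 10)))
            s = score_interictal(_alarms(mins), duration_s=7200.0)
            assert s.warned_time_min <= 120.0 + 1e-9
            assert s.fp_count <= len(mins)


class TestChanceSensitivity:
    def test_zero_warning_zero_sensitivity(self):
        assert chance_sensitivity(0.0) == 0.0

    def test_printed_value_rho_035(self):
        # 5-of-5 patient at 35% warning time: Snc^5 must equal 0.0031
        snc = chance_sensitivity(0.35)
        assert snc == pytest.approx(0.3150, abs=1e-4)
        assert snc**5 == pytest.approx(0.0031, abs=1e-4)

    def test_strictly_increasing_in_rho(self):
        grid = np.linspace(0.05, 0.95, 19)
        vals = [chance_sensitivity(r) for r in grid]
        assert np.all(np.diff(vals) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            chance_sensitivity(1.0)


class TestChancePValue:
    def test_n_zero_gives_one(self):
        assert chance_p_value(0, 2, 0.3) == 1.0

    def test_all_predicted_is_power(self):
        snc = chance_sensitivity(0.35)
        assert chance_p_value(5, 5, snc) == pytest.approx(snc**5, abs=1e-15)

    def test_n_gt_N_rejected(self):
        with pytest.raises(ValueError):
            chance_p_value(3, 2, 0.1)

    @pytest.mark.parametrize("N", [1, 3, 5, 8, 12])
    def test_matches_brute_force_enumeration(self, N):
        """Binomial tail equals enumeration over all 2^N outcome sequences."""
        snc = 0.37
        for n in range(N + 1):
            brute = 0.0
            for outcome in itertools.product([0, 1], repeat=N):
                if sum(outcome) >= n:
                    brute += snc ** sum(outcome) * (1 - snc) ** (N - sum(outcome))
            assert chance_p_value(n, N, snc) == pytest.approx(brute, abs=1e-12)


class TestAggregateReport:
    def _scores(self, n_pred, N, fp=0, inter_min=60.0, warned=0.0):
        pre = [PreictalScore(i < n_pred, 30.0 if i < n_pred else None)
               for i in range(N)]
        inter = [InterictalScore(fp_count=fp, warned_time_min=warned,
                                 duration_min=inter_min)]
        return pre, inter

    def test_pooled_sensitivity_weighted_by_seizures(self):
        rep = aggregate_report(
            {"a": self._scores(2, 2), "b": self._scores(1, 2)}
        )
        assert rep.pooled["sens_pct"] == pytest.approx(75.0)

    def test_headline_ratio_arithmetic(self):
        scores = {f"p{i}": self._scores(4, 4) for i in range(21)}
        # 84 of 87: distribute 3 misses
        scores["p0"] = self._scores(3, 4)
        scores["p1"] = self._scores(3, 4)
        scores["p2"] = self._scores(3, 4)
        scores["p20"] = self._scores(7, 7)
        rep = aggregate_report(scores)
        assert rep.pooled["n_seizures"] == 87
        assert rep.pooled["n_predicted"] == 84
        assert rep.pooled["sens_pct"] == pytest.approx(96.55, abs=0.01)

    def test_no_fps_zero_rates(self):
        rep = aggregate_report({"a": self._scores(2, 2)})
        row = rep.per_patient.iloc[0]
        assert row["fps_per_h"] == 0.0
        assert row["fp_pct"] == 0.0
        assert row["p_value"] == 0.0  # Snc = 0, n = N = 2

    def test_report_schema(self):
        rep = aggregate_report({"a": self._scores(1, 2, fp=1, warned=40.0)})
        assert list(rep.per_patient.columns) == [
            "patient", "n_seizures", "interictal_h", "sens_pct",
            "det_lat_min", "fps_per_h", "fp_pct", "p_value",
        ]

    def test_p_value_uses_measured_warning_fraction(self):
        pre, inter = self._scores(2, 2, fp=1, inter_min=100.0, warned=35.0)
        rep = aggregate_report({"a": (pre, inter)})
        snc = chance_sensitivity(0.35)
        assert rep.per_patient.iloc[0]["p_value"] == pytest.approx(
            chance_p_value(2, 2, snc), abs=1e-12
        )


class TestSensitivityFphCurve:
    def test_curve_points_and_monotonicity(self):
        # fake evaluator: higher threshold -> fewer alarms and lower sens
        def evaluate_at(thr):
            from hhtseizure.evaluation import EvaluationReport
            import pandas as pd

            return EvaluationReport(
                per_patient=pd.DataFrame(),
                pooled={"fps_per_h": 1.0 - thr, "sens_pct": 100.0 * (1.0 - thr)},
            )

        curve = sensitivity_fph_curve(evaluate_at, [0.0, 0.25, 0.5, 1.0])
        assert len(curve) == 4
        assert np.all(np.diff(curve["sens_pct"]) <= 0)
        assert np.all(np.diff(curve["fps_per_h"]) <= 0)
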