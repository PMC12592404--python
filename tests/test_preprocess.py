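import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magest.datamodel import Modality, Session, Task, TrialRecord
from magest.errors import DegenerateDesignError, ValidationError
from magest.preprocess import (
    baseline_fit_table,
    detect_outliers,
    fit_line,
    normalize_responses,
)


def normal_equations(x, y):
    """Closed-form OLS oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    rmse = np.sqrt((resid**2).sum() / (len(x) - 2))
    return slope, intercept, rmse


class TestFitLine:
    def test_identity(self):
        x = [490.0, 580.0, 670.0, 760.0, 850.0]
        fit = fit_line(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_perceived(self):
        fit = fit_line([1.0, 2.0, 3.0], [7.0, 7.0, 7.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(7.0)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_line([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_residual_mean_is_zero(self, rng):
        x = rng.uniform(400, 900, 50)
        y = 0.7 * x + 100 + rng.normal(0, 30, 50)
        fit = fit_line(x, y)
        assert abs(np.mean(fit.residuals)) <= 1e-9 * np.abs(y).mean()

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(1, 100, 20)
        y = r.normal(2 * x + 5, 10)
        fit = fit_line(x, y)
        slope, intercept, rmse = normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)
        assert fit.rmse == pytest.approx(rmse, abs=1e-10 * max(rmse, 1.0))


def participant_trials(cfg, responses_by_cell):
    """Build one temporal participant from {(session, modality): responses}."""
    out = []
    for (session, modality), responses in responses_by_cell.items():
        values = cfg.stimulus_set(Task.TEMPORAL, modality).values
        for i, resp in enumerate(responses):
            out.append(
                TrialRecord(
                    participant_id="P01",
                    task=Task.TEMPORAL,
                    session=session,
                    modality=modality,
                    stimulus=values[i % len(values)],
                    response=resp,
                    trial_index=i,
                )
            )
    return out


class TestNormalizeResponses:
    def make(self, cfg, shift_audio=0.0):
        rng = np.random.default_rng(0)
        cells = {}
        for session, modality in [
            (Session.AUDIO, Modality.A),
            (Session.VISION, Modality.V),
            (Session.INTERLEAVED, Modality.A),
            (Session.INTERLEAVED, Modality.V),
        ]:
            values = cfg.stimulus_set(Task.TEMPORAL, modality).values
            resp = [values[i % len(values)] + float(rng.normal(0, 20)) for i in range(18)]
            if (session, modality) == (Session.AUDIO, Modality.A):
                resp = [r + shift_audio for r in resp]
            cells[(session, modality)] = resp
        return participant_trials(cfg, cells)

    def test_fixed_point(self, cfg):
        trials = self.make(cfg)
        once = normalize_responses(trials, cfg)
        twice = normalize_responses(once, cfg)
        for a, b in zip(once, twice):
            assert a.response == pytest.approx(b.response, abs=1e-9)

    def test_cell_shift_cancels(self, cfg):
        base = normalize_responses(self.make(cfg), cfg)
        shifted = normalize_responses(self.make(cfg, shift_audio=250.0), cfg)
        for a, b in zip(base, shifted):
            assert a.response == pytest.approx(b.response, abs=1e-9)

    def test_slope_invariant(self, cfg):
        trials = self.make(cfg)
        norm = normalize_responses(trials, cfg)
        raw_audio = [t for t in trials if t.session is Session.AUDIO]
        norm_audio = [t for t in norm if t.session is Session.AUDIO]
        f_raw = fit_line([t.stimulus for t in raw_audio], [t.response for t in raw_audio])
        f_norm = fit_line([t.stimulus for t in norm_audio], [t.response for t in norm_audio])
        assert f_norm.slope == pytest.approx(f_raw.slope, abs=1e-12)

    def test_within_cell_variance_preserved(self, cfg):
        trials = self.make(cfg)
        norm = normalize_responses(trials, cfg)
        for session, modality in {(t.session, t.modality) for t in trials}:
            raw = [t.response for t in trials if (t.session, t.modality) == (session, modality)]
            out = [t.response for t in norm if (t.session, t.modality) == (session, modality)]
            assert np.var(out) == pytest.approx(np.var(raw), rel=1e-12)

    def test_missing_baseline_rejected(self, cfg):
        trials = self.make(cfg)
        audio_only = [t for t in trials if t.session is Session.AUDIO]
        with pytest.raises(ValidationError, match="baseline"):
            normalize_responses(audio_only, cfg)

    def test_small_cell_named(self, cfg):
        trials = self.make(cfg)
        trimmed = [t for t in trials if not (t.session is Session.VISION and t.trial_index > 0)]
        with pytest.raises(ValidationError, match="vision"):
            normalize_responses(trimmed, cfg)


def rmse_table(rmses_by_participant):
    rows = []
    for pid, sessions in rmses_by_participant.items():
        for session, rmse in sessions.items():
            rows.append(
                {"participant_id": pid, "task": "temporal", "session": session, "rmse": rmse}
            )
    return pd.DataFrame(rows)


class TestDetectOutliers:
    def test_all_equal_nobody_excluded(self):
        table = rmse_table({f"P{i}": {"audio": 50.0, "vision": 60.0} for i in range(5)})
        report = detect_outliers(table)
        assert not report.table["excluded"].any()
        assert report.excluded_for(Task.TEMPORAL) == frozenset()

    def test_single_session_spike_excludes_whole_task(self):
        base = {f"P{i:02d}": {"audio": 50.0 + i, "vision": 60.0 + i} for i in range(15)}
        base["P99"] = {"audio": 52.0, "vision": 60.0 * 20}
        report = detect_outliers(rmse_table(base))
        assert report.excluded_for(Task.TEMPORAL) == frozenset({"P99"})

    def test_flag_matches_rule_exactly(self):
        rng = np.random.default_rng(3)
        base = {f"P{i:02d}": {"audio": float(rng.uniform(40, 70))} for i in range(12)}
        base["P90"] = {"audio": 2000.0}
        report = detect_outliers(rmse_table(base), threshold=3.0)
        for row in report.table.itertuples(index=False):
            assert row.excluded == (
                row.group_sd > 0
                and abs(row.rmse - row.group_median) > 3.0 * row.group_sd
            )

    def test_cohort_21_to_19_temporal_20_spatial(self):
        # Two temporal spikes and one spatial spike in a 21-person cohort.
        rows = []
        rng = np.random.default_rng(9)
        for i in range(21):
            pid = f"P{i:02d}"
            for task, sessions, scale in (
                ("temporal", ("audio", "vision"), 50.0),
                ("spatial", ("audio", "vision"), 4.0),
            ):
                for s in sessions:
                    rmse = float(rng.uniform(0.9, 1.1)) * scale
                    if task == "temporal" and (
                        (pid == "P19" and s in ("audio", "vision")) or (pid == "P20" and s == "vision")
                    ):
                        rmse *= 20.0
                    if task == "spatial" and pid == "P18" and s == "audio":
                        rmse *= 20.0
                    rows.append(
                        {"participant_id": pid, "task": task, "session": s, "rmse": rmse}
                    )
        report = detect_outliers(pd.DataFrame(rows))
        assert report.excluded_for(Task.TEMPORAL) == frozenset({"P19", "P20"})
        assert report.excluded_for(Task.SPATIAL) == frozenset({"P18"})
        # analyzed sample sizes: 19 temporal, 20 spatial
        assert 21 - len(report.excluded_for(Task.TEMPORAL)) == 19
        assert 21 - len(report.excluded_for(Task.SPATIAL)) == 20

    def test_fewer_than_three_participants_rejected(self):
        table = rmse_table({"P1": {"audio": 50.0}, "P2": {"audio": 55.0}})
        with pytest.raises(ValidationError):
            detect_outliers(table)

    def test_rescreening_retained_cohort_is_consistent(self):
        rng = np.random.default_rng(4)
        base = {f"P{i:02d}": {"audio": float(rng.uniform(40, 70))} for i in range(15)}
        base["P90"] = {"audio": 5000.0}
        first = detect_outliers(rmse_table(base))
        retained = {
            k: v for k, v in base.items() if k not in first.excluded_for(Task.TEMPORAL)
        }
        second = detect_outliers(rmse_table(retained))
        for row in second.table.itertuples(index=False):
            assert row.excluded == (
                row.group_sd > 0
                and abs(row.rmse - row.group_median) > 3.0 * row.group_sd
            )


class TestBaselineFitTable:
    def test_fits_per_participant_and_session(self, small_cohort):
        table = baseline_fit_table(small_cohort)
        assert set(table["session"]) == {"audio", "vision"}
        assert len(table) == 2 * table["participant_id"].nunique()
        assert (table["rmse"] >= 0).all()
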