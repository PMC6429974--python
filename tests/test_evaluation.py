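"""Evaluation protocol: smoothing, metric oracles, aggregation, trends,
and the LOSO bootstrap guarantees on a small synthetic cohort."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

import pulsestage as ps
from pulsestage.evaluation import (
    EvalConfig,
    PredictionTrace,
    aggregate_cohort,
    round_classes,
)


def make_trace(averaged, labels, times=None, lbnp_onset=10.0, end=None,
               reason="presyncope"):
    averaged = np.asarray(averaged, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = averaged.size
    times = np.asarray(times, dtype=float) if times is not None else np.arange(n, dtype=float)
    return PredictionTrace(
        subject_id="T", end_reason=reason, times_s=times, true_labels=labels,
        raw=np.tile(labels[:, None], (1, 2)),
        smoothed=np.tile(averaged[:, None], (1, 2)), averaged=averaged,
        baseline_start_s=float(times[0]), lbnp_onset_s=lbnp_onset,
        protocol_end_s=float(end if end is not None else times[-1]),
    )


class TestMovingAverage:
    def test_constant_and_window_one(self):
        x = np.full(50, 2.0)
        assert np.allclose(ps.moving_average(x, 20), 2.0)
        y = np.arange(30.0)
        assert np.array_equal(ps.moving_average(y, 1), y)

    def test_unit_step_closed_form(self):
        x = np.zeros(100)
        step = 40
        x[step:] = 1.0
        out = ps.moving_average(x, 20)
        for j in range(20):
            assert out[step + j] == pytest.approx((j + 1) / 20)
        assert np.allclose(out[step + 20:], 1.0)
        assert np.allclose(out[:step], 0.0)

    def test_partial_history_at_start(self):
        x = np.arange(1.0, 8.0)
        out = ps.moving_average(x, 3)
        assert out[0] == 1.0 and out[1] == 1.5 and out[2] == 2.0

    def test_never_widens_range(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, 500).astype(float)
        out = ps.moving_average(x, 20)
        assert out.min() >= x.min() and out.max() <= x.max()

    def test_smooth_then_average_commutes_with_average_then_smooth(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(0, 4, (200, 10)).astype(float)
        a = np.column_stack([ps.moving_average(raw[:, j], 20)
                             for j in range(10)]).mean(axis=1)
        b = ps.moving_average(raw.mean(axis=1), 20)
        assert np.allclose(a, b, atol=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            ps.moving_average(np.array([]), 20)


class TestConfusionAndKappa:
    def test_confusion_hand_tally(self):
        true = [0, 0, 1, 1, 1, 2, 2, 3, 3, 3, 3, 0]
        pred = [0, 1, 1, 1, 2, 2, 2, 3, 3, 2, 3, 0]
        conf = ps.confusion_matrix(true, pred)
        expected = np.array([[2, 1, 0, 0],
                             [0, 2, 1, 0],
                             [0, 0, 2, 0],
                             [0, 0, 1, 3]])
        assert np.array_equal(conf, expected)
        assert conf.sum() == len(true)

    def test_perfect_and_single_column(self):
        t = np.repeat(np.arange(4), 5)
        assert np.array_equal(np.diag(np.diag(ps.confusion_matrix(t, t))),
                              ps.confusion_matrix(t, t))
        conf0 = ps.confusion_matrix(t, np.zeros_like(t))
        assert conf0[:, 1:].sum() == 0

    def test_kappa_diagonal_is_one_uniform_is_zero(self):
        assert ps.cohen_kappa(np.diag([5, 1, 7, 2])) == pytest.approx(1.0)
        assert ps.cohen_kappa(np.full((4, 4), 3)) == pytest.approx(0.0)

    def test_kappa_degenerate_single_cell_is_zero(self):
        conf = np.zeros((4, 4), dtype=int)
        conf[2, 2] = 10
        assert ps.cohen_kappa(conf) == 0.0

    def test_label_validation(self):
        with pytest.raises(ValueError):
            ps.confusion_matrix([0, 4], [0, 0])
        with pytest.raises(ValueError):
            ps.cohen_kappa(np.zeros((4, 4)))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_kappa_matches_label_pair_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        conf = rng.integers(0, 20, (4, 4))
        if conf.sum() == 0 or np.isclose(
            float(conf.sum(1) @ conf.sum(0)) / conf.sum() ** 2, 1.0
        ):
            return
        true = np.repeat(np.arange(16) // 4, conf.ravel())
        pred = np.repeat(np.arange(16) % 4, conf.ravel())
        assert ps.cohen_kappa(conf) == pytest.approx(
            cohen_kappa_score(true, pred, labels=[0, 1, 2, 3]), abs=1e-12
        )


class TestPerClassMetrics:
    def test_perfect_trace(self):
        labels = np.repeat(np.arange(4), 10)
        m = ps.per_class_metrics(make_trace(labels.astype(float), labels))
        assert np.allclose(m["accuracy"], 100.0)
        assert np.allclose(m["mse"], 0.0)
        assert m["overall_accuracy"] == 100.0

    def test_half_offset_rounds_down_tie_rule(self):
        labels = np.zeros(10, dtype=int)
        m = ps.per_class_metrics(make_trace(np.full(10, 0.5), labels))
        assert m["accuracy"][0] == 100.0        # 0.5 rounds to class 0
        assert m["mse"][0] == pytest.approx(0.25)

    def test_hand_computed_eight_beat_trace(self):
        averaged = np.array([0.0, 0.2, 1.4, 0.8, 2.0, 2.6, 3.0, 2.4])
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        m = ps.per_class_metrics(make_trace(averaged, labels))
        # rounded: 0,0,1,1,2,3,3,2
        assert m["accuracy"].tolist() == [100.0, 100.0, 50.0, 50.0]
        assert m["mse"][0] == pytest.approx((0.0 + 0.04) / 2)
        assert m["mse"][1] == pytest.approx((0.16 + 0.04) / 2)
        assert m["mse"][2] == pytest.approx((0.0 + 0.36) / 2)
        assert m["mse"][3] == pytest.approx((0.0 + 0.36) / 2)
        assert m["overall_accuracy"] == pytest.approx(75.0)

    def test_absent_class_reported_nan(self):
        m = ps.per_class_metrics(make_trace([0.0, 1.0], [0, 1]))
        assert np.isnan(m["accuracy"][3]) and np.isnan(m["mse"][3])

    def test_rounding_boundaries(self):
        x = np.array([-0.4, 0.49, 0.5, 0.51, 1.5, 2.5, 3.4])
        assert round_classes(x).tolist() == [0, 0, 0, 1, 1, 2, 3]


class TestAggregateCohort:
    def subject(self, acc0):
        return {
            "accuracy": np.array([acc0, 50.0, 40.0, 60.0]),
            "mse": np.array([0.1, 0.3, 0.4, 0.2]),
            "overall_accuracy": 55.0,
            "overall_mse": 0.25,
        }

    def test_single_subject_median_iqr(self):
        df = aggregate_cohort({"A": self.subject(90.0)}, pooled_kappa=0.5)
        assert df.loc["accuracy", "class_0_median"] == 90.0
        assert df.loc["accuracy", "class_0_iqr"] == 0.0
        assert df.attrs["kappa"] == 0.5

    def test_three_subject_percentiles(self):
        per = {s: self.subject(a) for s, a in zip("ABC", (90.0, 95.0, 100.0))}
        df = aggregate_cohort(per, pooled_kappa=0.4)
        assert df.loc["accuracy", "class_0_median"] == 95.0
        assert df.loc["accuracy", "class_0_iqr"] == pytest.approx(5.0)

    def test_layout_has_all_classes_and_overall(self):
        df = aggregate_cohort({"A": self.subject(90.0)}, pooled_kappa=0.1)
        assert list(df.index) == ["mse", "accuracy"]
        for c in range(4):
            assert f"class_{c}_median" in df.columns
        assert "overall_median" in df.columns

    def test_pooled_kappa_is_kappa_of_summed_confusions(self):
        rng = np.random.default_rng(2)
        c1, c2 = rng.integers(0, 30, (2, 4, 4))
        pooled = ps.cohen_kappa(c1 + c2)
        mean_of = 0.5 * (ps.cohen_kappa(c1) + ps.cohen_kappa(c2))
        assert pooled != pytest.approx(mean_of)  # definitions differ


class TestSeverityTrend:
    def test_rising_trace_is_increase(self):
        n = 200
        t = np.arange(n, dtype=float)
        avg = np.concatenate([np.zeros(50), np.linspace(0, 3, n - 50)])
        trace = make_trace(avg, np.zeros(n, dtype=int), times=t, lbnp_onset=50.0)
        assert ps.severity_trend(trace) == "increase"

    def test_flat_trace_is_stagnation(self):
        n = 200
        trace = make_trace(np.full(n, 1.0), np.zeros(n, dtype=int),
                           lbnp_onset=50.0)
        assert ps.severity_trend(trace) == "stagnation"

    def test_early_rise_then_plateau_is_stagnation(self):
        # the tolerant phenotype: above baseline but no further progression
        n = 300
        avg = np.concatenate([np.zeros(50), np.linspace(0, 2, 50),
                              np.full(200, 2.0)])
        trace = make_trace(avg, np.zeros(n, dtype=int), lbnp_onset=50.0)
        assert ps.severity_trend(trace) == "stagnation"

    def test_missing_baseline_rejected(self):
        trace = make_trace(np.ones(50), np.zeros(50, dtype=int), lbnp_onset=-1.0)
        with pytest.raises(ValueError, match="baseline"):
            ps.severity_trend(trace)


@pytest.fixture(scope="module")
def run(tiny_matrix):
    cfg = EvalConfig(seed=3)
    return cfg, ps.loso_bootstrap_evaluate(tiny_matrix, cfg)


class TestLosoBootstrap:
    def test_deterministic_under_fixed_seed(self, tiny_matrix, run):
        cfg, (traces, _) = run
        traces2, _ = ps.loso_bootstrap_evaluate(tiny_matrix, cfg)
        for s in traces:
            assert np.array_equal(traces[s].raw, traces2[s].raw)
            assert np.array_equal(traces[s].averaged, traces2[s].averaged)

    def test_traces_bounded_and_aligned(self, tiny_matrix, run):
        _, (traces, _) = run
        for s, t in traces.items():
            assert t.averaged.min() >= 0.0 and t.averaged.max() <= 3.0
            n = len(tiny_matrix.for_subject(s))
            assert t.raw.shape == (n, 10)
            assert t.averaged.size == n

    def test_every_subject_evaluated_tolerated_never_trains(self, tiny_matrix,
                                                            run):
        _, (traces, report) = run
        assert set(traces) == set(tiny_matrix.subjects)
        tol = [s for s in tiny_matrix.subjects
               if tiny_matrix.end_reasons[s] == "tolerated"]
        # pooled metrics cover presyncope subjects only
        n_pre = sum(len(tiny_matrix.for_subject(s)) for s in tiny_matrix.subjects
                    if s not in tol)
        assert report.pooled_confusion.sum() == n_pre

    def test_c_and_k_sweeps_reuse_identical_draws(self, tiny_matrix):
        cfg = EvalConfig(seed=5, n_bootstrap=2)
        small = dataclasses.replace(cfg)
        t1, _ = ps.loso_bootstrap_evaluate(tiny_matrix, small, C=0.01, k=3)
        t2, _ = ps.loso_bootstrap_evaluate(tiny_matrix, small, C=0.1, k=3)
        # same subsamples, different C: raw predictions may differ, but the
        # evaluated beat sets are identical
        for s in t1:
            assert np.array_equal(t1[s].times_s, t2[s].times_s)

    def test_needs_three_presyncope_subjects(self, tiny_matrix):
        two = tiny_matrix.subset(
            np.isin(tiny_matrix.subject_ids, tiny_matrix.subjects[:2])
        )
        with pytest.raises(ValueError, match="3 presyncope"):
            ps.loso_bootstrap_evaluate(two, EvalConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EvalConfig(subsample_fraction=0.0)
        with pytest.raises(ValueError):
            EvalConfig(smooth_window_beats=0)
        with pytest.raises(ValueError):
            EvalConfig(C_grid=(0.01, -1.0))


class TestSweeps:
    def test_c_grid_sweep_emits_one_report_per_C(self, tiny_matrix):
        cfg = EvalConfig(seed=5, n_bootstrap=2, C_grid=(0.01, 0.1))
        out = ps.c_grid_sweep(tiny_matrix, cfg)
        assert sorted(out) == [0.01, 0.1]
        for _, rep in out.values():
            assert np.isfinite(rep.pooled_kappa)

    def test_component_addition_reports_every_k(self, tiny_matrix):
        cfg = EvalConfig(seed=5, n_bootstrap=2)
        df = ps.component_addition_curve(tiny_matrix, [2, 4], cfg)
        assert list(df.index) == [2, 4]
        assert df["kappa"].notna().all()

    def test_component_addition_input_validation(self, tiny_matrix):
        with pytest.raises(ValueError):
            ps.component_addition_curve(tiny_matrix, [0, 5])
        with pytest.raises(ValueError):
            ps.component_addition_curve(tiny_matrix, [5, 2])
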