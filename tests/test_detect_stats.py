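"""Classification, online flagging and paired-test statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from icgperf.bolus_metrics import BolusMetrics, ConditionSummary, METRIC_NAMES
from icgperf.detect_stats import (
    DetectionThresholds,
    OnlineDetector,
    classify_condition,
    cohort_report,
    format_report_text,
    online_detect,
    paired_t_test,
)
from icgperf.pipeline import run_cohort, run_subject
from icgperf.synthgen import high_snr_scenario

from conftest import paired_t_oracle


def _summary(label, slopes, n_expected=None, detected=None):
    detected = [True] * len(slopes) if detected is None else detected
    vals = [s for s, d in zip(slopes, detected) if d]
    n_exp = n_expected or len(slopes)
    s = ConditionSummary(
        label=label, n_expected=n_exp, n_detected=len(vals)
    )
    for m in METRIC_NAMES:
        s.mean[m] = float(np.mean(vals)) if vals else float("nan")
        s.sd[m] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
    return s


def _bolus(slope, detected=True):
    return BolusMetrics(
        detected=detected,
        slope=slope if detected else float("nan"),
        f_max=slope * 8 if detected else float("nan"),
        t_0=1.0,
        t_max=8.0,
        t_half_max=3.0,
        tr=0.375,
    )


class TestClassifyCondition:
    def test_identical_to_baseline_is_normal(self):
        base = _summary("baseline", [1.2, 1.5, 1.3])
        res = classify_condition(base, base)
        assert res.category == "normal"
        assert res.slope_ratio == pytest.approx(1.0)

    def test_zero_detected_is_absent(self):
        base = _summary("baseline", [1.2, 1.5, 1.3])
        gone = _summary("severe", [], n_expected=6)
        res = classify_condition(gone, base)
        assert res.category == "absent"
        assert res.slope_ratio == 0.0

    def test_reduced_slope_is_decreased(self):
        base = _summary("baseline", [1.4, 1.4, 1.4])
        low = _summary("mild", [0.5, 0.6, 0.55])
        assert classify_condition(low, base).category == "decreased"

    def test_underprimed_baseline_rejected(self):
        base = _summary("baseline", [1.2], n_expected=6)
        with pytest.raises(ValueError, match="baseline"):
            classify_condition(base, base)

    def test_monotone_in_condition_severity(self):
        """Lowering the true slope distribution never flips decreased back
        to normal (paired seeds, same thresholds)."""
        for seed in (1, 2, 3):
            cats = []
            for level in (1.0, 0.6, 0.35, 0.15):
                res = run_cohort(
                    1,
                    ("baseline", "mild"),
                    seed=seed,
                    use_frames=False,
                    scenario_overrides={"within_cv_scale": 0.3},
                )
                # rescale: replay classification with scaled condition mean
                sub = res.subjects[0]
                summ = sub.summaries["mild"]
                scaled = _summary(
                    "mild",
                    [level * summ.mean["slope"]] * summ.n_detected,
                    n_expected=summ.n_expected,
                )
                cats.append(
                    classify_condition(
                        scaled, sub.summaries["baseline"]
                    ).category
                )
            order = {"normal": 0, "decreased": 1, "absent": 2}
            ranks = [order[c] for c in cats]
            assert ranks == sorted(ranks)


class TestOnlineDetect:
    def test_stream_at_baseline_mean_never_flagged(self):
        base = _summary("baseline", [1.4, 1.4, 1.4])
        flags = online_detect([_bolus(1.4)] * 6, base)
        assert not flags.any()

    def test_all_undetected_all_flagged(self):
        base = _summary("baseline", [1.4, 1.4, 1.4])
        flags = online_detect([_bolus(0, detected=False)] * 6, base)
        assert flags.all()

    def test_first_flag_at_occlusion_boundary(self):
        """With low within-subject dispersion the first flagged bolus is the
        first post-occlusion bolus, per generator condition labels."""
        for seed in (4, 5, 6):
            res = run_subject(
                high_snr_scenario(
                    labels=("baseline", "severe"),
                    seed=seed,
                    subject_factor=1.0,
                    within_cv_scale=0.2,
                ),
                use_frames=False,
            )
            central = [m for m in res.metrics if m.roi_label == "central"]
            det = OnlineDetector(res.summaries["baseline"])
            flags = [det.update(m) for m in central]
            first_severe = next(
                i for i, m in enumerate(central) if m.condition == "severe"
            )
            assert flags.index(True) == first_severe

    def test_online_offline_agreement_on_controlled_streams(self):
        """A condition is decreased offline iff >=50% of its boluses are
        flagged online, in the low-dispersion operating regime."""
        base = _summary("baseline", [1.4, 1.35, 1.45, 1.4])
        thr = DetectionThresholds()
        for slopes in ([0.5] * 6, [1.4] * 6, [0.5] * 4 + [1.4] * 2, [1.3] * 6):
            summ = _summary("test", slopes)
            offline = classify_condition(summ, base, thr).category
            online_frac = online_detect(
                [_bolus(s) for s in slopes], base, thr
            ).mean()
            assert (offline == "decreased") == (online_frac >= 0.5)


class TestPairedTTest:
    def test_identical_samples(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_example_against_formula_oracle(self):
        x = (1.2, 2.0, 3.1)
        y = (0.9, 1.4, 2.2)
        r = paired_t_test(x, y)
        t_ref, p_ref = paired_t_oracle(x, y)
        assert r.t == pytest.approx(t_ref, abs=1e-12)
        assert r.p == pytest.approx(p_ref, abs=1e-12)
        assert r.df == 2

    def test_hundred_random_inputs_match_oracle_to_1e10(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(2, 12)
            x = rng.normal(1.0, 1.0, n)
            y = x - rng.normal(0.5, 0.7, n)
            r = paired_t_test(x, y)
            t_ref, p_ref = paired_t_oracle(x, y)
            assert abs(r.t - t_ref) < 1e-10
            assert abs(r.p - p_ref) < 1e-10

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2, 1, 8)
        y = rng.normal(1, 1, 8)
        r = paired_t_test(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.t == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_zero_variance(self):
        r = paired_t_test([2.0, 2.0], [1.0, 1.0])
        assert r.p == 0.0 and r.degenerate
        r0 = paired_t_test([1.0, 1.0], [1.0, 1.0])
        assert r0.t == 0.0 and r0.p == 1.0 and not r0.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


class TestCohortReport:
    def test_single_subject_report_echoes_summary(self):
        res = run_cohort(1, ("baseline", "severe"), seed=2, use_frames=False)
        rep = res.report
        sub = res.subjects[0]
        pooled = rep["conditions"][0]["pooled"]["slope"]
        assert pooled["mean"] == pytest.approx(
            sub.summaries["baseline"].mean["slope"]
        )
        assert pooled["n"] == sub.summaries["baseline"].n_detected
        text = format_report_text(rep)
        assert "(M = " in text and "SD = " in text

    def test_empty_condition_marked_absent_not_crash(self):
        from types import SimpleNamespace

        base = _summary("baseline", [1.2, 1.4, 1.3])
        gone = _summary("severe", [], n_expected=6)
        sub = SimpleNamespace(
            subject_id=1,
            organ="spleen",
            summaries={"baseline": base, "severe": gone},
            detections={"severe": classify_condition(gone, base)},
        )
        rep = cohort_report([sub])
        assert rep["per_organ_counts"]["severe"]["spleen"] == "1/1"
        assert rep["conditions"][1]["pooled"]["slope"]["n"] == 0
        assert "absent" in format_report_text(rep)

    def test_pooled_sd_matches_direct_pooling(self):
        res = run_cohort(3, ("baseline", "severe"), seed=3, use_frames=False)
        direct = res.pooled_slopes("baseline")
        pooled = res.report["conditions"][0]["pooled"]["slope"]
        assert pooled["mean"] == pytest.approx(direct.mean())
        assert pooled["sd"] == pytest.approx(direct.std(ddof=1))
        assert pooled["n"] == len(direct)
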