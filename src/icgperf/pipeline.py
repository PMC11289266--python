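"""End-to-end drivers: simulate -> track/extract -> metrics -> detect -> report.

``run_subject`` processes one synthetic recording with two tracked regions of
interest (a central and a peripheral ROI on the organ) and returns everything
the cohort statistics need.  ``run_cohort`` builds a virtual multi-animal
study: per-subject scenarios share the protocol but differ in seed and in a
stratified animal-to-animal perfusion factor, mirroring the between-subject
spread that dominates pooled slope variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bolus_metrics import (
    BolusMetrics,
    ConditionSummary,
    compute_metrics,
    condition_summary,
    segment_boluses,
)
from .detect_stats import (
    DetectionResult,
    DetectionThresholds,
    classify_condition,
    cohort_report,
)
from .synthgen import (
    GroundTruth,
    ScenarioConfig,
    high_snr_scenario,
    simulate_curves,
    simulate_recording,
    stratified_subject_factors,
)
from .track_extract import ROI, TimeIntensityCurve, extract_curve, track_roi

__all__ = [
    "MetricParams",
    "SubjectResult",
    "CohortResult",
    "default_rois",
    "run_subject",
    "run_cohort",
    "subject_seed",
]


@dataclass(frozen=True)
class MetricParams:
    k_detect: float = 3.0
    m_consec: int = 3
    pre_window: float = 10.0
    eps_abs: float = 1e-6


@dataclass
class SubjectResult:
    subject_id: int
    organ: str
    ground_truth: GroundTruth
    curves: dict[str, TimeIntensityCurve]
    metrics: list[BolusMetrics]  # all ROIs, all boluses
    summaries: dict[str, ConditionSummary]  # per condition name, ROIs pooled
    detections: dict[str, DetectionResult]  # non-baseline conditions

    def slopes_for(self, condition: str) -> np.ndarray:
        return np.array(
            [
                m.slope
                for m in self.metrics
                if m.detected and m.condition == condition
            ]
        )


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    report: dict

    def pooled_slopes(self, condition: str) -> np.ndarray:
        return np.concatenate([s.slopes_for(condition) for s in self.subjects])


def default_rois(config: ScenarioConfig, half: int = 15) -> dict[str, ROI]:
    """A central ROI at the organ center and a peripheral one off-center."""
    h, w = config.image_size
    peripheral = (int(round(0.72 * h)), int(round(0.72 * w)))
    return {
        "central": ROI(center=(h // 2, w // 2), half_size=(half, half)),
        "peripheral": ROI(center=peripheral, half_size=(half, half)),
    }


def run_subject(
    config: ScenarioConfig,
    rois: dict[str, ROI] | None = None,
    metric_params: MetricParams = MetricParams(),
    thresholds: DetectionThresholds = DetectionThresholds(),
    search_radius: int = 8,
    subject_id: int = 0,
    organ: str = "organ",
    use_frames: bool = True,
) -> SubjectResult:
    """Run the full analysis chain on one simulated subject.

    ``use_frames=False`` switches to the curve-level fast path (identical
    kinetic ground truth, no imaging layer) for statistical replications.
    """
    if use_frames:
        stack, gt = simulate_recording(config)
        rois = rois or default_rois(config)
        curves = {}
        for label, roi in rois.items():
            track = track_roi(stack, roi, search_radius=search_radius)
            curves[label] = extract_curve(stack, track, roi_label=label)
    else:
        curves, gt = simulate_curves(config)

    schedule = gt.schedule
    all_metrics: list[BolusMetrics] = []
    for label, curve in curves.items():
        segs = segment_boluses(
            curve,
            schedule.injection_times,
            schedule.bolus_period,
            pre_window=metric_params.pre_window,
            conditions=schedule.injection_condition,
        )
        for seg in segs:
            all_metrics.append(
                compute_metrics(
                    seg,
                    k_detect=metric_params.k_detect,
                    m_consec=metric_params.m_consec,
                    eps_abs=metric_params.eps_abs,
                )
            )

    summaries = {
        name: condition_summary(
            [m for m in all_metrics if m.condition == name], label=name
        )
        for name in schedule.condition_names
    }

    baseline_name = schedule.condition_names[0]
    detections: dict[str, DetectionResult] = {}
    base = summaries[baseline_name]
    if base.n_detected >= 2:
        for name in schedule.condition_names[1:]:
            detections[name] = classify_condition(
                summaries[name], base, thresholds
            )

    return SubjectResult(
        subject_id=subject_id,
        organ=organ,
        ground_truth=gt,
        curves=curves,
        metrics=all_metrics,
        summaries=summaries,
        detections=detections,
    )


def subject_seed(seed: int, subject_index: int) -> int:
    """Deterministic per-subject scenario seed derived from a root seed."""
    ss = np.random.SeedSequence((seed, 7000 + subject_index))
    return int(ss.generate_state(1)[0] % (2**31))


def run_cohort(
    n_subjects: int,
    condition_labels: Sequence[str] = ("baseline", "severe"),
    seed: int = 1,
    organs: Sequence[str] | None = None,
    use_frames: bool = True,
    metric_params: MetricParams = MetricParams(),
    thresholds: DetectionThresholds = DetectionThresholds(),
    scenario_overrides: dict | None = None,
) -> CohortResult:
    """Simulate and analyse a virtual cohort under the high-SNR protocol.

    Subject factors are drawn by stratified sampling across the cohort so a
    handful of virtual animals spans the population spread reproducibly;
    each subject then receives its own scenario seed.
    """
    base_cfg = high_snr_scenario(labels=condition_labels)
    factors = stratified_subject_factors(n_subjects, base_cfg.subject_cv, seed)
    # design rank = rank of the subject's animal factor; the slope-quantile
    # blocks rotate against it so animal effect x bolus quantile pairing is
    # balanced across the cohort
    design_rank = np.argsort(np.argsort(factors))
    organs = list(organs) if organs else ["organ"] * n_subjects
    subjects = []
    for i in range(n_subjects):
        cfg = high_snr_scenario(
            labels=condition_labels,
            seed=subject_seed(seed, i),
            subject_factor=float(factors[i]),
            cohort_seed=seed,
            cohort_index=int(design_rank[i]),
            cohort_size=n_subjects,
            **(scenario_overrides or {}),
        )
        subjects.append(
            run_subject(
                cfg,
                metric_params=metric_params,
                thresholds=thresholds,
                subject_id=i + 1,
                organ=organs[i % len(organs)],
                use_frames=use_frames,
            )
        )
    baseline_name = subjects[0].ground_truth.schedule.condition_names[0]
    report = cohort_report(subjects, baseline=baseline_name)
    return CohortResult(subjects=subjects, report=report)
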