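"""Agreement and detection-performance metrics.

Covers the evaluation used for the RR estimator: event-level matching of
detected against true troughs/artifacts with the critical success index
(CSI), absolute error of the rate estimate, Bland-Altman limits of
agreement with the mean +- 2*std convention, and a per-subject paired
t-test between reference and estimated rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "MatchCounts",
    "BlandAltman",
    "TTestResult",
    "EvalReport",
    "match_events",
    "csi",
    "absolute_error",
    "bland_altman",
    "paired_t_test",
    "evaluate_trials",
    "DEFAULT_MATCH_TOLERANCE_S",
]

# Event-matching tolerance: localization jitter of a few samples around a
# cardiac trough is not a detection failure. 100 ms = 5 samples at 50 Hz.
DEFAULT_MATCH_TOLERANCE_S = 0.1


@dataclass(frozen=True)
class MatchCounts:
    """True-positive / false-negative / false-positive event counts."""

    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    std_diff: float
    loa_low: float
    loa_high: float
    pct_within: float

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "std_diff": self.std_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pct_within": self.pct_within,
        }


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    dof: int
    p_value: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


@dataclass
class EvalReport:
    """Cohort-level evaluation of estimated against reference rates."""

    per_trial_ae: np.ndarray
    per_subject_mean_ae: dict[str, float]
    overall_mean_ae: float
    bland_altman: BlandAltman
    t_tests: dict[str, TTestResult]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_trial_ae": self.per_trial_ae.tolist(),
            "per_subject_mean_ae": dict(self.per_subject_mean_ae),
            "overall_mean_ae": self.overall_mean_ae,
            "bland_altman": self.bland_altman.to_dict(),
            "t_tests": {k: v.to_dict() for k, v in self.t_tests.items()},
            "notes": list(self.notes),
        }


def match_events(
    true_indices: np.ndarray,
    detected_indices: np.ndarray,
    tolerance_samples: int,
) -> MatchCounts:
    """Greedy one-to-one nearest matching of detected to true events.

    Candidate pairs within ``tolerance_samples`` are matched in order of
    increasing distance, each event used at most once. Unmatched true events
    count as misses (FN), unmatched detections as false alarms (FP).
    """
    true_idx = np.asarray(true_indices, dtype=int)
    det_idx = np.asarray(detected_indices, dtype=int)
    if np.any(np.diff(true_idx) <= 0) or np.any(np.diff(det_idx) <= 0):
        raise ValidationError("event index lists must be strictly increasing")
    if tolerance_samples < 0:
        raise ValidationError("tolerance must be non-negative")
    pairs = [
        (abs(int(t) - int(d)), i, j)
        for i, t in enumerate(true_idx)
        for j, d in enumerate(det_idx)
        if abs(int(t) - int(d)) <= tolerance_samples
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        tp += 1
    return MatchCounts(tp=tp, fn=true_idx.size - tp, fp=det_idx.size - tp)


def csi(counts: MatchCounts) -> float:
    """Critical success index TP / (TP + FN + FP)."""
    denom = counts.tp + counts.fn + counts.fp
    if denom == 0:
        raise DegenerateInputError("CSI undefined: no events at all")
    return counts.tp / denom


def absolute_error(reference_rr: float, estimated_rr: float) -> float:
    """|reference - estimate| in BPM."""
    if not (np.isfinite(reference_rr) and np.isfinite(estimated_rr)):
        raise ValidationError("rates must be finite")
    if reference_rr < 0 or estimated_rr < 0:
        raise ValidationError("rates must be non-negative")
    return abs(reference_rr - estimated_rr)


def bland_altman(reference: np.ndarray, estimate: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement with limits at mean +- 2 * sample std.

    The multiplier is exactly 2 (not 1.96). ``pct_within`` is the percentage
    of differences falling inside the closed limits interval.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValidationError("reference and estimate must have equal length")
    if ref.size < 3:
        raise ValidationError("Bland-Altman needs at least 3 pairs")
    d = est - ref
    mean = float(np.mean(d))
    std = float(np.std(d, ddof=1))
    lo, hi = mean - 2.0 * std, mean + 2.0 * std
    within = float(np.mean((d >= lo) & (d <= hi)) * 100.0)
    return BlandAltman(mean_diff=mean, std_diff=std, loa_low=lo, loa_high=hi, pct_within=within)


def paired_t_test(reference: np.ndarray, estimate: np.ndarray) -> TTestResult:
    """Two-sided paired-samples t-test on estimate - reference.

    All-zero differences give t = 0, p = 1 by convention. Zero-variance
    differences with a nonzero mean are flagged degenerate (the statistic
    is unbounded).
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValidationError("reference and estimate must have equal length")
    n = ref.size
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    d = est - ref
    dof = n - 1
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(statistic=0.0, dof=dof, p_value=1.0)
        return TTestResult(
            statistic=float(np.inf) if mean > 0 else float(-np.inf),
            dof=dof,
            p_value=0.0,
            degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return TTestResult(statistic=float(t), dof=dof, p_value=p)


def evaluate_trials(
    reference: np.ndarray,
    estimate: np.ndarray,
    subjects: list[str] | None = None,
) -> EvalReport:
    """Cohort evaluation: per-trial AE, per-subject means and t-tests,
    overall mean AE, and Bland-Altman agreement.

    No multiple-comparison correction is applied to the per-subject tests;
    this is noted in the report metadata.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValidationError("reference and estimate must have equal length")
    if subjects is None:
        subjects = ["all"] * ref.size
    if len(subjects) != ref.size:
        raise ValidationError("subjects list length mismatch")
    ae = np.abs(ref - est)
    per_subject: dict[str, float] = {}
    t_tests: dict[str, TTestResult] = {}
    for subj in dict.fromkeys(subjects):  # preserves first-seen order
        mask = np.asarray([s == subj for s in subjects])
        per_subject[subj] = float(ae[mask].mean())
        if mask.sum() >= 2:
            t_tests[subj] = paired_t_test(ref[mask], est[mask])
    return EvalReport(
        per_trial_ae=ae,
        per_subject_mean_ae=per_subject,
        overall_mean_ae=float(ae.mean()),
        bland_altman=bland_altman(ref, est),
        t_tests=t_tests,
        notes=["no multiple-comparison correction applied to per-subject t-tests"],
    )
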