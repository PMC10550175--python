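"""Analysis procedures for the pre/post training study.

Covers the learning-gain arithmetic (e_delta = e1 - e0, negative =
improvement), IQR-based outlier filtering, paired one-tailed and Welch
t-tests, the transfer/suitability correlation battery over condition strata,
gaze-derived mean eye-tooth distance, the screen-coverage estimate, and the
hand-tool calibration math (pose offsets with angle differences wrapped to
[-180, 180] degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "ParticipantRecord",
    "Pose",
    "GazeSample",
    "UndefinedTest",
    "learning_gain",
    "simulator_gain",
    "iqr_outlier_filter",
    "paired_t_one_tailed",
    "welch_t",
    "transfer_analyses",
    "mean_eye_tooth_distance",
    "screen_coverage_fraction",
    "calibration_offset",
    "angle_delta",
]

#: The four study conditions: 3D rendering mode x hand-tool alignment.
GROUPS = ("stereo_aligned", "mono_aligned", "stereo_misaligned", "mono_misaligned")


class UndefinedTest(ValueError):
    """A test statistic is undefined for the given data (zero variance)."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: condition group, pre/post expert errors, six trial scores."""

    group: str
    e0: float  # pre-test mean expert error
    e1: float  # post-test mean expert error
    trial_scores: tuple[float, ...]  # six Dentist scores, trial order
    mean_eye_tooth_cm: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.e0 < 0 or self.e1 < 0:
            raise ValueError("expert errors must be nonnegative")
        scores = tuple(float(t) for t in self.trial_scores)
        if len(scores) != 6:
            raise ValueError(f"expected six trial scores, got {len(scores)}")
        object.__setattr__(self, "trial_scores", scores)

    @property
    def stereo(self) -> bool:
        return self.group.startswith("stereo")

    @property
    def aligned(self) -> bool:
        return self.group.endswith("_aligned")


@dataclass(frozen=True)
class Pose:
    """Rigid pose: position in cm, rotation as Euler angles in degrees."""

    position: tuple[float, float, float]
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        pos = tuple(float(v) for v in self.position)
        rot = tuple(float(v) for v in self.rotation)
        if not all(np.isfinite(pos)) or not all(np.isfinite(rot)):
            raise ValueError("pose components must be finite")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "rotation", rot)


@dataclass(frozen=True)
class GazeSample:
    """One gaze log row: cyclops-eye position, tooth hit position, hit flag (cm)."""

    time: float
    eye_position: tuple[float, float, float]
    tooth_hit: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hit: bool = True


# ---------------------------------------------------------------------------
# learning gain and filtering


def learning_gain(record: ParticipantRecord) -> float:
    """Inverse learning gain e_delta = e1 - e0 (negative = improvement)."""
    return record.e1 - record.e0


def simulator_gain(record: ParticipantRecord) -> float:
    """In-simulator gain: trial-6 score minus trial-1 score (negative = improvement)."""
    return record.trial_scores[5] - record.trial_scores[0]


def iqr_outlier_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (numpy's default percentile method).
    Returns ``(kept, removed)`` in original order.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("IQR filtering needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


# ---------------------------------------------------------------------------
# t-tests


def paired_t_one_tailed(pre, post, direction: str = "less") -> tuple[float, int, float]:
    """Paired one-tailed t-test on post - pre differences.

    ``direction="less"`` tests the hypothesis that post values are lower than
    their paired pre values (improvement on an error scale).  Returns
    ``(t, df, p)`` with df = n - 1.  Zero variance of the differences leaves
    the statistic undefined.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or len(pre) < 3:
        raise ValueError("need paired samples of equal length n >= 3")
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    diffs = post - pre
    if np.allclose(diffs.std(ddof=1), 0):
        raise UndefinedTest("paired t undefined: zero variance of differences")
    res = stats.ttest_rel(post, pre, alternative=direction)
    return float(res.statistic), len(pre) - 1, float(res.pvalue)


def welch_t(a, b, alternative: str = "two-sided") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite (fractional) df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        raise UndefinedTest("Welch t undefined: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# transfer / suitability correlations


def _strata(records: list[ParticipantRecord]):
    yield "all", records
    yield "stereo", [r for r in records if r.stereo]
    yield "mono", [r for r in records if not r.stereo]
    yield "aligned", [r for r in records if r.aligned]
    yield "misaligned", [r for r in records if not r.aligned]
    for g in GROUPS:
        yield g, [r for r in records if r.group == g]


def transfer_analyses(
    records: list[ParticipantRecord],
    initial_performance: str = "day1_mean",
) -> pd.DataFrame:
    """Suitability and learning-transfer correlations per condition stratum.

    For each stratum (all samples, by rendering mode, by alignment, by
    group) computes Pearson r and p for

    * ``suitability`` — pre-training expert error e0 vs initial simulator
      performance (mean of the day-1 trials 1-3 by default, or trial 1 only
      with ``initial_performance="trial1"``), and
    * ``transfer`` — real learning gain e_delta vs simulator gain
      (trial 6 - trial 1).

    Strata with fewer than 3 records are omitted with a note.
    """
    if initial_performance not in ("day1_mean", "trial1"):
        raise ValueError(f"unknown initial_performance {initial_performance!r}")
    rows = []
    for name, recs in _strata(records):
        for analysis in ("suitability", "transfer"):
            if len(recs) < 3:
                rows.append(
                    dict(stratum=name, analysis=analysis, n=len(recs), r=np.nan, p=np.nan,
                         note="stratum too small (n < 3)")
                )
                continue
            if analysis == "suitability":
                x = np.array([r.e0 for r in recs])
                if initial_performance == "day1_mean":
                    y = np.array([np.mean(r.trial_scores[:3]) for r in recs])
                else:
                    y = np.array([r.trial_scores[0] for r in recs])
            else:
                x = np.array([learning_gain(r) for r in recs])
                y = np.array([simulator_gain(r) for r in recs])
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(dict(stratum=name, analysis=analysis, n=len(recs),
                                 r=np.nan, p=np.nan, note="zero variance"))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(dict(stratum=name, analysis=analysis, n=len(recs),
                             r=float(r), p=float(p), note=""))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gaze and screen coverage


def mean_eye_tooth_distance(samples: list[GazeSample]) -> float:
    """Mean Euclidean eye-to-tooth-hit distance (cm) over hit samples only."""
    dists = [
        float(np.linalg.norm(np.subtract(s.eye_position, s.tooth_hit)))
        for s in samples
        if s.hit
    ]
    if not dists:
        raise UndefinedTest("no gaze samples hit the tooth")
    return float(np.mean(dists))


def screen_coverage_fraction(region_px: tuple[int, int], display_px: tuple[int, int]) -> float:
    """Percentage of the display area covered by a pixel region."""
    rw, rh = region_px
    dw, dh = display_px
    if dw <= 0 or dh <= 0:
        raise ValueError("display dimensions must be positive")
    if rw <= 0 or rh <= 0:
        raise ValueError("region dimensions must be positive")
    return 100.0 * (rw * rh) / (dw * dh)


# ---------------------------------------------------------------------------
# hand-tool calibration


def angle_delta(a, b) -> tuple[float, float, float]:
    """Componentwise Euler-angle difference a - b wrapped into [-180, 180] degrees.

    The wrap uses round-half-even on the turn count, so +180 stays +180 and
    -180 stays -180.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    wrapped = d - 360.0 * np.round(d / 360.0)
    return tuple(float(v) for v in wrapped)


def calibration_offset(
    mirror: Pose,
    delta_p: tuple[float, float, float],
    delta_theta: tuple[float, float, float],
    controller: Pose,
) -> Pose:
    """Offset to apply to the VR camera so virtual and physical tools align.

    The virtual controller target is the mirror origin shifted by the
    hand-measured offset: p_CT = p_M + delta_p, theta_CT = theta_M +
    delta_theta (angles simply added).  The returned pose is the correction
    p_VR' = p_CT - p_C with theta_VR' the wrapped angle difference between
    theta_CT and the physical controller angles theta_C.
    """
    p_ct = np.asarray(mirror.position) + np.asarray(delta_p, dtype=float)
    th_ct = np.asarray(mirror.rotation) + np.asarray(delta_theta, dtype=float)
    p_off = p_ct - np.asarray(controller.position)
    th_off = angle_delta(th_ct, controller.rotation)
    return Pose(position=tuple(float(v) for v in p_off), rotation=th_off)
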