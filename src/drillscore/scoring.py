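"""Automated scoring of drilling outcomes.

The core is the *Dentist* metric D: a weighted, rescaled and flipped
combination of sensitivity S and precision P, placed on the 0–15 expert
rubric scale (0 = ideal outcome, lower is better).  With the voxel tallies
of :func:`drillscore.volume.classify_outcome`,

    P = TP / (TP + FP)        (penalizes under-drilling)
    S = TP / (TP + FN)        (penalizes over-drilling)

the two components are linearly rescaled to occupy comparable ranges,
anchored at the empirically observed lower ends P = 0.95 and S = 0.2:

    P~ = (P - 0.95) / (1 - 0.95)
    S~ = (S - 0.2)  / (1 - 0.2)

and combined as

    D = (1 - (1.5 S~ + P~) / 2.5) * 15

which has the algebraically equivalent closed form in raw counts

    D = 15 (32 FP TP + 3 FN TP + 35 FN FP) / (4 (TP + FN)(TP + FP)).

No clamping is applied: scores outside the empirical component windows
(P in (0.96, 0.995], S in (0.2, 1)) yield D outside [0, 15] and emit a
warning, keeping the two forms exactly equivalent.

The module also provides the F1 baseline, a suite of standard binary
classification metrics, and the essential-outcome selection used to pick a
small expert-rateable subset uniformly covering the observed score range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import ClassificationCounts

__all__ = [
    "ComponentScores",
    "DentistScore",
    "UndefinedScoreError",
    "component_scores",
    "dentist_score",
    "dentist_score_from_counts",
    "f1_score",
    "metric_suite",
    "select_essential_outcomes",
    "polynomial_trend",
]

P_ANCHOR = 0.95  # precision value mapped to P~ = 0
S_ANCHOR = 0.2  # sensitivity value mapped to S~ = 0

# empirically observed component windows; out-of-window values warn
P_WINDOW = (0.96, 0.995)
S_WINDOW = (0.2, 1.0)


class UndefinedScoreError(ZeroDivisionError):
    """A score's denominator is zero for the given counts."""


@dataclass(frozen=True)
class ComponentScores:
    """Precision/sensitivity and their linear rescalings (unclamped)."""

    P: float
    S: float

    @property
    def P_tilde(self) -> float:
        return (self.P - P_ANCHOR) / (1.0 - P_ANCHOR)

    @property
    def S_tilde(self) -> float:
        return (self.S - S_ANCHOR) / (1.0 - S_ANCHOR)


@dataclass(frozen=True)
class DentistScore:
    """Dentist metric value on the expert rubric scale (0 ideal, 15 at the anchors)."""

    value: float


def _check_denominators(counts: ClassificationCounts) -> None:
    if counts.TP + counts.FP == 0:
        raise UndefinedScoreError("precision undefined: TP + FP = 0 (no material retained)")
    if counts.TP + counts.FN == 0:
        raise UndefinedScoreError("sensitivity undefined: TP + FN = 0 (nothing should remain)")


def component_scores(counts: ClassificationCounts) -> ComponentScores:
    """Precision and sensitivity of an outcome, with their rescalings."""
    _check_denominators(counts)
    p = counts.TP / (counts.TP + counts.FP)
    s = counts.TP / (counts.TP + counts.FN)
    if not (P_WINDOW[0] < p <= P_WINDOW[1]) or not (S_WINDOW[0] < s <= S_WINDOW[1]):
        warnings.warn(
            f"component scores outside the empirical windows (P={p:.4f}, S={s:.4f}); "
            "the Dentist score may fall outside [0, 15]",
            stacklevel=2,
        )
    return ComponentScores(P=p, S=s)


def dentist_score(components: ComponentScores) -> DentistScore:
    """Dentist metric from rescaled components: D = (1 - (1.5 S~ + P~)/2.5) * 15."""
    st, pt = components.S_tilde, components.P_tilde
    if not (np.isfinite(st) and np.isfinite(pt)):
        raise ValueError("components must be finite")
    return DentistScore(value=(1.0 - (1.5 * st + pt) / 2.5) * 15.0)


def dentist_score_from_counts(counts: ClassificationCounts) -> DentistScore:
    """Dentist metric directly from counts (closed form, equivalent to the rescaled form)."""
    _check_denominators(counts)
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    num = 15.0 * (32.0 * fp * tp + 3.0 * fn * tp + 35.0 * fn * fp)
    den = 4.0 * (tp + fn) * (tp + fp)
    return DentistScore(value=num / den)


def f1_score(counts: ClassificationCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN), the harmonic mean of sensitivity and precision."""
    den = 2 * counts.TP + counts.FP + counts.FN
    if den == 0:
        raise UndefinedScoreError("F1 undefined: 2TP + FP + FN = 0")
    return 2 * counts.TP / den


# ---------------------------------------------------------------------------
# standard metric suite


def _safe_div(num: float, den: float, reason: str):
    if den == 0:
        return None, reason
    return num / den, None


def metric_suite(counts: ClassificationCounts) -> dict[str, dict]:
    """A declared superset of the standard binary-classification metrics.

    Returns ``{name: {"value": float | None, "reason": str | None}}``.
    Metrics whose denominator vanishes for the given counts are reported as
    missing with a reason, never silently as 0.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    n = counts.total
    out: dict[str, dict] = {}

    def put(name, value, reason=None):
        out[name] = {"value": None if value is None else float(value), "reason": reason}

    acc, r = _safe_div(tp + tn, n, "no voxels")
    put("accuracy", acc, r)
    tpr, r_tpr = _safe_div(tp, tp + fn, "TP+FN=0")
    tnr, r_tnr = _safe_div(tn, tn + fp, "TN+FP=0")
    ppv, r_ppv = _safe_div(tp, tp + fp, "TP+FP=0")
    npv, r_npv = _safe_div(tn, tn + fn, "TN+FN=0")
    put("sensitivity", tpr, r_tpr)
    put("recall", tpr, r_tpr)
    put("specificity", tnr, r_tnr)
    put("precision", ppv, r_ppv)
    put("npv", npv, r_npv)
    if tpr is None or tnr is None:
        put("balanced_accuracy", None, "sensitivity or specificity undefined")
        put("informedness", None, "sensitivity or specificity undefined")
        put("g_mean", None, "sensitivity or specificity undefined")
    else:
        put("balanced_accuracy", (tpr + tnr) / 2)
        put("informedness", tpr + tnr - 1)
        put("g_mean", float(np.sqrt(tpr * tnr)))
    if ppv is None or npv is None:
        put("markedness", None, "PPV or NPV undefined")
    else:
        put("markedness", ppv + npv - 1)
    f1, r = _safe_div(2 * tp, 2 * tp + fp + fn, "2TP+FP+FN=0")
    put("f1", f1, r)
    jac, r = _safe_div(tp, tp + fp + fn, "TP+FP+FN=0")
    put("jaccard", jac, r)
    ts, r = _safe_div(tp, tp + fn + fp, "TP+FN+FP=0")
    put("threat_score", ts, r)
    if ppv is None or tpr is None:
        put("fowlkes_mallows", None, "precision or recall undefined")
    else:
        put("fowlkes_mallows", float(np.sqrt(ppv * tpr)))
    mcc_den = float(np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    if mcc_den == 0:
        put("mcc", None, "a marginal is zero")
    else:
        put("mcc", (tp * tn - fp * fn) / mcc_den)
    # Cohen's kappa from the 2x2 table
    po, r = _safe_div(tp + tn, n, "no voxels")
    if po is None:
        put("cohen_kappa", None, r)
    else:
        pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
        if pe == 1.0:
            put("cohen_kappa", None, "degenerate marginals (pe=1)")
        else:
            put("cohen_kappa", (po - pe) / (1 - pe))
    prev, r = _safe_div(tp + fn, n, "no voxels")
    put("prevalence", prev, r)
    fpr = None if tnr is None else 1 - tnr
    fnr = None if tpr is None else 1 - tpr
    put("fpr", fpr, r_tnr if fpr is None else None)
    put("fnr", fnr, r_tpr if fnr is None else None)
    put("fdr", None if ppv is None else 1 - ppv, r_ppv if ppv is None else None)
    put("for", None if npv is None else 1 - npv, r_npv if npv is None else None)
    if tpr is None or fpr is None:
        put("lr_plus", None, "TPR or FPR undefined")
    else:
        lr_plus, r = _safe_div(tpr, fpr, "FPR=0")
        put("lr_plus", lr_plus, r)
    if fnr is None or tnr is None:
        put("lr_minus", None, "FNR or TNR undefined")
    else:
        lr_minus, r = _safe_div(fnr, tnr, "TNR=0")
        put("lr_minus", lr_minus, r)
    lrp = out["lr_plus"]["value"]
    lrm = out["lr_minus"]["value"]
    if lrp is None or lrm is None:
        put("diagnostic_odds_ratio", None, "likelihood ratio undefined")
    else:
        dor, r = _safe_div(lrp, lrm, "LR-=0")
        put("diagnostic_odds_ratio", dor, r)
    if tpr is None or fpr is None:
        put("prevalence_threshold", None, "TPR or FPR undefined")
    elif tpr == fpr:
        put("prevalence_threshold", None, "TPR=FPR")
    else:
        put("prevalence_threshold", (np.sqrt(tpr * fpr) - fpr) / (tpr - fpr))
    return out


# ---------------------------------------------------------------------------
# essential-outcome selection


def select_essential_outcomes(scores, k: int) -> list[int]:
    """Pick ``k`` sample indices whose scores uniformly cover the score range.

    The interval [min, max] is partitioned into ``k`` equal-width bins; from
    each nonempty bin the sample nearest the bin center is taken (ties go to
    the lowest index).  For an empty bin, the globally unused sample nearest
    that bin center is taken instead.  The returned indices are distinct and
    their scores reach from the lowest to the highest bin of the range.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    if k > len(np.unique(scores)):
        raise ValueError(f"k={k} exceeds number of distinct scores")
    lo, hi = float(scores.min()), float(scores.max())
    width = (hi - lo) / k if hi > lo else 0.0
    centers = lo + (np.arange(k) + 0.5) * width if width > 0 else np.full(k, lo)
    if width > 0:
        bins = np.minimum(((scores - lo) / width).astype(int), k - 1)
    else:
        bins = np.zeros(n, dtype=int)
    chosen: list[int] = []
    used = np.zeros(n, dtype=bool)
    empty_bins: list[int] = []
    for b in range(k):
        members = np.flatnonzero(bins == b)
        if len(members) == 0:
            empty_bins.append(b)
            continue
        dist = np.abs(scores[members] - centers[b])
        idx = int(members[np.argmin(dist)])  # argmin ties -> lowest index
        chosen.append(idx)
        used[idx] = True
    for b in empty_bins:
        free = np.flatnonzero(~used)
        idx = int(free[np.argmin(np.abs(scores[free] - centers[b]))])
        chosen.append(idx)
        used[idx] = True
    return sorted(chosen)


def polynomial_trend(x, y, degree: int = 3) -> np.ndarray:
    """Fitted values of an illustrative polynomial regression of y on x.

    Used to visualize the curvature of metric-vs-expert relationships; the
    degree is configurable and the fit is descriptive, not inferential.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    return np.polynomial.polynomial.polyval(x, coeffs)
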