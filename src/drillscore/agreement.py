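"""Expert rubric encoding and inter-rater / auto-vs-expert agreement statistics.

An expert rates a drilling outcome on five surfaces (the four cardinal tooth
walls and the pulp floor), each with an integer error category:

    +0  access to all orifices without an excess cavity
    +1  access to all orifices with minor over-drilling
    +2  incomplete removal of the pulp-chamber roof and/or excessive over-drilling
    +3  unidentified canals and/or perforation

The total error is the sum over the five surfaces, ranging 0–15 with lower
values better; with two raters the mean total (possibly half-integer) is the
working score.  Agreement between raters — and between the automated score
and the expert scale — is quantified with Cohen's kappa, the two-way
random-effects intraclass correlation (ICC), the information-based measure
of disagreement (IBMD), and Pearson correlation.

The IBMD for paired nonnegative ratings x_i, y_i is

    IBMD = mean_i  log(|x_i - y_i| + 1) / log(max(x_i, y_i) + 1)

with the pair term defined as 0 when x_i = y_i = 0 (natural logarithms);
it is 0 iff every pair agrees and grows with disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "ExpertRating",
    "AgreementReport",
    "UndefinedStatistic",
    "expert_total_error",
    "mean_expert_error",
    "cohens_kappa",
    "icc_two_rater",
    "ibmd",
    "pearson_correlation",
    "agreement_report",
]

SURFACES = ("mesial", "distal", "buccal", "lingual", "pulp_floor")


class UndefinedStatistic(ValueError):
    """The statistic is undefined for the given data (degenerate variance/marginals)."""


@dataclass(frozen=True)
class ExpertRating:
    """One rater's five per-surface error categories (each in {0, 1, 2, 3})."""

    surface_errors: tuple[int, int, int, int, int]
    rater_id: str = ""

    def __post_init__(self) -> None:
        errs = tuple(int(e) for e in self.surface_errors)
        if len(errs) != 5 or any(e not in (0, 1, 2, 3) for e in errs):
            raise ValueError(
                f"surface_errors must be five integers in 0..3, got {self.surface_errors!r}"
            )
        object.__setattr__(self, "surface_errors", errs)

    def total(self) -> int:
        return sum(self.surface_errors)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement statistics between two score series (None = undefined)."""

    kappa: float | None
    icc: float | None
    ibmd: float | None
    pearson_r: float | None
    pearson_p: float | None
    n: int

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "icc": self.icc,
            "ibmd": self.ibmd,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "n": self.n,
        }


def expert_total_error(rating: ExpertRating) -> int:
    """Total rubric error: sum of the five surface categories, in [0, 15]."""
    return rating.total()


def mean_expert_error(ratings: list[ExpertRating]) -> float:
    """Mean of the raters' total errors for one outcome (half-integer for two raters)."""
    if not ratings:
        raise ValueError("at least one rating is required")
    return float(np.mean([r.total() for r in ratings]))


def cohens_kappa(rater_a, rater_b, weighting: str = "none") -> float:
    """Cohen's kappa between two integer score vectors.

    ``weighting="linear"`` is the sensible default for ordinal 0–15 totals;
    ``"none"`` gives the classical unweighted kappa.  Degenerate data where
    both raters use a single identical category leave kappa undefined.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be 1D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired scores")
    if weighting not in ("none", "linear"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        raise UndefinedStatistic("kappa undefined: a single category used by both raters")
    weights = None if weighting == "none" else "linear"
    return float(cohen_kappa_score(a, b, weights=weights))


def icc_two_rater(rater_a, rater_b, model: str = "ICC(2,1)") -> float:
    """Two-way random-effects intraclass correlation for two raters.

    ``ICC(2,1)`` is absolute agreement of single ratings (the default);
    ``ICC(2,k)`` is absolute agreement of the k-rater mean.  Computed from
    the standard two-way ANOVA mean squares (subjects x raters, n x k):

        ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)
        ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    where MS_R, MS_C, MS_E are the row (subject), column (rater) and residual
    mean squares.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be 1D and of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if model not in ("ICC(2,1)", "ICC(2,k)"):
        raise ValueError(f"unknown model {model!r}")
    data = np.column_stack([a, b])  # n subjects x k raters
    k = data.shape[1]
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0 or not np.isfinite(ms_r):
        raise UndefinedStatistic("ICC undefined: zero between-subject variance")
    if model == "ICC(2,1)":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    else:
        denom = ms_r + (ms_c - ms_e) / n
    if denom == 0:
        raise UndefinedStatistic("ICC undefined: zero denominator")
    return float((ms_r - ms_e) / denom)


def ibmd(x, y) -> float:
    """Information-based measure of disagreement between paired nonnegative scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score vectors must be 1D and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("IBMD requires nonnegative scores")
    terms = np.zeros(len(x))
    mx = np.maximum(x, y)
    nonzero = mx > 0
    terms[nonzero] = np.log(np.abs(x[nonzero] - y[nonzero]) + 1.0) / np.log(mx[nonzero] + 1.0)
    return float(terms.mean())


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatistic("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def agreement_report(
    x,
    y,
    kappa_weighting: str = "linear",
    icc_model: str = "ICC(2,1)",
) -> AgreementReport:
    """Bundle of all agreement statistics for two paired score series.

    Statistics that are undefined for the data are reported as None rather
    than raising, so a single degenerate statistic does not void the report.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 paired scores")

    def tryget(fn):
        try:
            return fn()
        except (UndefinedStatistic, ValueError):
            return None

    kappa = tryget(lambda: cohens_kappa(np.round(x).astype(int), np.round(y).astype(int), kappa_weighting))
    icc = tryget(lambda: icc_two_rater(x, y, icc_model))
    ib = tryget(lambda: ibmd(x, y))
    rp = tryget(lambda: pearson_correlation(x, y))
    r, p = rp if rp is not None else (None, None)
    return AgreementReport(kappa=kappa, icc=icc, ibmd=ib, pearson_r=r, pearson_p=p, n=n)
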