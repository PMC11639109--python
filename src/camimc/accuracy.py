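"""Diagnostic-test-accuracy statistics.

2x2-table estimators (sensitivity, specificity, predictive values) with
exact Clopper-Pearson confidence intervals, likelihood ratios with
log-normal (Simel) intervals, ROC curves for ordinal scores, the
Mann-Whitney / trapezoidal AUROC with the DeLong variance, Youden-index
cut-off selection, and Cohen's kappa for paired raters.

The unit of analysis throughout is the single observation (one index
assessment paired with the same-day reference diagnosis).  Repeated
observations of the same patient are treated as independent, matching
the primary analysis these estimators support; confidence intervals are
anti-conservative under within-patient clustering (a warning is logged
by the model layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ProportionEstimate",
    "RatioEstimate",
    "RocPoint",
    "RocCurve",
    "AurocEstimate",
    "KappaEstimate",
    "AccuracyEstimates",
    "LikelihoodRatios",
    "build_confusion",
    "clopper_pearson",
    "accuracy_estimates",
    "likelihood_ratios",
    "roc_points",
    "auroc",
    "delong_ci",
    "youden_optimal",
    "cohen_kappa",
]


def _z(alpha: float) -> float:
    # full-precision normal quantile; rounding happens only at display
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 table of an index test against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Reference-positive observations."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Reference-negative observations."""
        return self.fp + self.tn


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with an exact confidence interval."""

    x: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "clopper_pearson"


@dataclass(frozen=True)
class RatioEstimate:
    """A likelihood ratio with a log-normal confidence interval.

    ``degenerate`` flags tables with an empty cell, where the point or
    its interval is infinite or undefined (reported as ``inf``/``nan``,
    never as a silent finite number).
    """

    point: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "log_normal"
    degenerate: bool = False


class RocPoint(NamedTuple):
    cutoff: float
    sensitivity: float
    fpr: float


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points for an ordinal score, one per candidate cut-off.

    Points are ordered by increasing cut-off, so sensitivity and the
    false-positive rate are non-increasing along the list; the curve is
    anchored at (FPR 1, sens 1) and (FPR 0, sens 0).
    """

    points: tuple

    def to_arrays(self):
        """Return (cutoffs, sensitivities, fprs) as numpy arrays."""
        a = np.asarray(self.points, dtype=float)
        return a[:, 0], a[:, 1], a[:, 2]


@dataclass(frozen=True)
class AurocEstimate:
    """Area under the ROC curve (c-statistic) with DeLong uncertainty."""

    auc: float
    se: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    alpha: float = 0.05
    method: str = "trapezoid"


@dataclass(frozen=True)
class KappaEstimate:
    """Cohen's kappa for two raters on a binary rating.

    ``defined`` is False when both raters are constant and identical
    (chance agreement 1), where kappa has no value.
    """

    kappa: float
    p_o: float
    p_e: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    alpha: float = 0.05
    defined: bool = True


def build_confusion(
    index_positive: Sequence, reference_positive: Sequence
) -> ConfusionCounts:
    """Cross-tabulate index-test positivity against the reference diagnosis."""
    a = np.asarray(index_positive, dtype=bool)
    b = np.asarray(reference_positive, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("index and reference must be 1-d sequences of equal length")
    if a.size == 0:
        raise ValueError("cannot build a confusion table from empty input")
    return ConfusionCounts(
        tp=int(np.sum(a & b)),
        fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)),
        tn=int(np.sum(~a & ~b)),
    )


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> ProportionEstimate:
    """Exact (Clopper-Pearson) binomial confidence interval.

    Uses the beta-quantile formulation: the lower bound is the
    ``alpha/2`` quantile of Beta(x, n - x + 1) and the upper bound the
    ``1 - alpha/2`` quantile of Beta(x + 1, n - x), with the boundary
    conventions ``x = 0 -> ci_low = 0`` and ``x = n -> ci_high = 1``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return ProportionEstimate(x=int(x), n=int(n), point=x / n,
                              ci_low=lo, ci_high=hi, alpha=alpha)


@dataclass(frozen=True)
class AccuracyEstimates:
    """Sensitivity, specificity and predictive values for one 2x2 table.

    An estimate whose denominator is zero is undefined and reported as
    ``None``.
    """

    counts: ConfusionCounts
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]
    alpha: float = 0.05


def accuracy_estimates(counts: ConfusionCounts, alpha: float = 0.05) -> AccuracyEstimates:
    """Estimate sensitivity, specificity, PPV and NPV with exact CIs."""
    def _est(x: int, n: int) -> Optional[ProportionEstimate]:
        return clopper_pearson(x, n, alpha) if n > 0 else None

    return AccuracyEstimates(
        counts=counts,
        sensitivity=_est(counts.tp, counts.tp + counts.fn),
        specificity=_est(counts.tn, counts.tn + counts.fp),
        ppv=_est(counts.tp, counts.tp + counts.fp),
        npv=_est(counts.tn, counts.tn + counts.fn),
        alpha=alpha,
    )


@dataclass(frozen=True)
class LikelihoodRatios:
    lr_pos: RatioEstimate
    lr_neg: RatioEstimate


def likelihood_ratios(counts: ConfusionCounts, alpha: float = 0.05) -> LikelihoodRatios:
    """Positive and negative likelihood ratios with log-method CIs.

    LR+ = sens / (1 - spec), LR- = (1 - sens) / spec.  The interval is
    ``exp(ln LR +- z * se)`` with ``se(ln LR+) = sqrt(1/tp - 1/(tp+fn) +
    1/fp - 1/(fp+tn))`` and the analogous expression (fn, tn in place of
    tp, fp) for LR-.  A zero cell in the numerator or denominator makes
    the ratio or its interval degenerate: LR+ is infinite when fp = 0
    and LR- is zero when fn = 0, both flagged rather than silently
    finite.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    m, n = tp + fn, fp + tn
    if m == 0 or n == 0:
        raise ValueError("likelihood ratios need both reference classes present")
    z = _z(alpha)
    sens, spec = tp / m, tn / n

    def _ratio(num_cell: int, den_cell: int, point: float) -> RatioEstimate:
        # num_cell / den_cell are the cells entering the log-variance
        if den_cell == 0:
            return RatioEstimate(math.inf, math.nan, math.inf, alpha,
                                 degenerate=True)
        if num_cell == 0:
            return RatioEstimate(0.0, 0.0, math.nan, alpha, degenerate=True)
        se = math.sqrt(1 / num_cell - 1 / m + 1 / den_cell - 1 / n)
        return RatioEstimate(
            point=point,
            ci_low=math.exp(math.log(point) - z * se),
            ci_high=math.exp(math.log(point) + z * se),
            alpha=alpha,
        )

    lr_pos = _ratio(tp, fp, sens / (1 - spec) if spec < 1 else math.inf)
    lr_neg = _ratio(fn, tn, (1 - sens) / spec if spec > 0 else math.inf)
    return LikelihoodRatios(lr_pos=lr_pos, lr_neg=lr_neg)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative label")


def roc_points(scores: Sequence, labels: Sequence) -> RocCurve:
    """ROC operating points over every candidate integer cut-off.

    A record is classified positive when ``score >= c`` for each
    ``c`` from ``min(score)`` (everything positive: sens 1, FPR 1) to
    ``max(score) + 1`` (nothing positive: sens 0, FPR 0).
    """
    s = np.asarray(scores)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    _check_two_classes(y)
    m = int(y.sum())
    n = int(y.size - m)
    pts = []
    for c in range(int(s.min()), int(s.max()) + 2):
        pred = s >= c
        pts.append(RocPoint(
            cutoff=float(c),
            sensitivity=float((pred & y).sum() / m),
            fpr=float((pred & ~y).sum() / n),
        ))
    return RocCurve(points=tuple(pts))


def _mann_whitney_auc(s: np.ndarray, y: np.ndarray) -> float:
    # midrank formulation: P(X_pos > X_neg) + 1/2 P(tie)
    m = int(y.sum())
    n = int(y.size - m)
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - m * (m + 1) / 2) / (m * n))


def auroc(scores: Sequence, labels: Sequence) -> AurocEstimate:
    """Area under the ROC curve (point estimate).

    Computed twice — trapezoidal integration of the threshold-sweep
    curve and the Mann-Whitney midrank statistic — and the two routes
    are asserted equal, guarding both against tie-handling mistakes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    _check_two_classes(y)
    curve = roc_points(np.asarray(scores), labels)
    _, sens, fpr = curve.to_arrays()
    # reversed point order walks the staircase from (0,0) to (1,1);
    # tied scores appear as diagonal segments, integrated as midpoints
    trap = float(np.trapezoid(sens[::-1], fpr[::-1]))
    mw = _mann_whitney_auc(s, y)
    if not math.isclose(trap, mw, abs_tol=1e-10):
        raise AssertionError(
            f"trapezoidal ({trap}) and Mann-Whitney ({mw}) AUROC disagree"
        )
    return AurocEstimate(auc=mw, method="trapezoid=mann_whitney")


def _placements(s_pos: np.ndarray, s_neg: np.ndarray):
    """DeLong placement values via sorted searches (no m*n outer product)."""
    neg_sorted = np.sort(s_neg)
    pos_sorted = np.sort(s_pos)
    n, m = s_neg.size, s_pos.size
    below = np.searchsorted(neg_sorted, s_pos, side="left")
    equal = np.searchsorted(neg_sorted, s_pos, side="right") - below
    v10 = (below + 0.5 * equal) / n
    above = m - np.searchsorted(pos_sorted, s_neg, side="right")
    eq = np.searchsorted(pos_sorted, s_neg, side="right") - np.searchsorted(
        pos_sorted, s_neg, side="left"
    )
    v01 = (above + 0.5 * eq) / m
    return v10, v01


def delong_ci(scores: Sequence, labels: Sequence, alpha: float = 0.05) -> AurocEstimate:
    """AUROC with the DeLong variance and a normal-approximation CI.

    The variance is ``S10/m + S01/n`` where S10 and S01 are the sample
    variances of the positive and negative placement values and m, n the
    class sizes.  The interval is truncated to [0, 1]; a perfectly
    separating score has se = 0 and a collapsed interval.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    m = int(y.sum())
    n = int(y.size - m)
    if m < 2 or n < 2:
        raise ValueError(f"DeLong variance needs >= 2 per class, got {m} and {n}")
    v10, v01 = _placements(s[y], s[~y])
    auc = float(v10.mean())
    var = float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)
    se = math.sqrt(max(var, 0.0))
    z = _z(alpha)
    return AurocEstimate(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        alpha=alpha,
        method="delong",
    )


def youden_optimal(points: Sequence) -> int:
    """Cut-off maximising the Youden index J = sensitivity + specificity - 1.

    ``points`` is a sequence of ``(cutoff, sensitivity, specificity)``
    triples.  Ties are broken toward the lowest cut-off, favouring
    sensitivity (a screening instrument should not miss cases).
    """
    pts = list(points)
    if not pts:
        raise ValueError("need at least one candidate cut-off")
    best = min(pts, key=lambda t: (-(t[1] + t[2] - 1.0), t[0]))
    return int(best[0]) if float(best[0]).is_integer() else best[0]


def cohen_kappa(
    rater_a: Sequence, rater_b: Sequence, alpha: float = 0.05
) -> KappaEstimate:
    """Cohen's kappa for two raters' binary ratings of the same subjects.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and the
    chance agreement p_e from the marginal rating rates.  The standard
    error is the large-sample (Fleiss-Cohen-Everitt) formula and the CI
    a normal approximation.  When both raters are constant and
    identical, p_e = 1 and kappa is undefined (``defined=False``).
    """
    a = np.asarray(rater_a, dtype=bool)
    b = np.asarray(rater_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be 1-d sequences of equal length")
    n = a.size
    if n < 2:
        raise ValueError("kappa needs at least two paired observations")

    # 2x2 table of proportions, rows = rater a, cols = rater b
    p = np.empty((2, 2))
    for i, av in enumerate((False, True)):
        for j, bv in enumerate((False, True)):
            p[i, j] = np.sum((a == av) & (b == bv)) / n
    pa = p.sum(axis=1)  # rater a marginals
    pb = p.sum(axis=0)  # rater b marginals
    p_o = float(p[0, 0] + p[1, 1])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        return KappaEstimate(
            kappa=math.nan, p_o=p_o, p_e=p_e, se=math.nan,
            ci_low=math.nan, ci_high=math.nan, n=n, alpha=alpha, defined=False,
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt large-sample variance
    term_diag = sum(
        p[i, i] * (1.0 - (pa[i] + pb[i]) * (1.0 - kappa)) ** 2 for i in range(2)
    )
    term_off = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (pb[i] + pa[j]) ** 2
        for i in range(2) for j in range(2) if i != j
    )
    term_c = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (term_diag + term_off - term_c) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = _z(alpha)
    return KappaEstimate(
        kappa=float(kappa), p_o=p_o, p_e=p_e, se=se,
        ci_low=float(kappa - z * se), ci_high=float(kappa + z * se),
        n=n, alpha=alpha,
    )
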