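"""Agreement and diagnostic statistics for binary cluster classification.

Covers the full evaluation layer used to compare an automated screener
against pathologists on the same set of clusters: confusion-matrix metrics,
Cohen's kappa with its large-sample standard error and Wald 95% CI plus the
six qualitative interpretation bands, one-way random-effects ICC (whose
average-measures form satisfies the identity ICC = 1 - 1/F), empirical ROC
curves with trapezoidal AUC and the Hanley-McNeil standard error, the
DeLong paired AUC Z-test, the Youden-optimal cutoff, and the seeded
0.8:0.2 train/validation split.

Label convention throughout the package: 1 = cancer cluster, 0 = non-cancer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix entries must be >= 0")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one item")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Derived rates; entries are ``None`` when the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float


def confusion_metrics(cm: ConfusionMatrix) -> ConfusionMetrics:
    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return ConfusionMetrics(
        sensitivity=_rate(cm.tp, cm.tp + cm.fn),
        specificity=_rate(cm.tn, cm.tn + cm.fp),
        ppv=_rate(cm.tp, cm.tp + cm.fp),
        npv=_rate(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.n,
    )


# --------------------------------------------------------------------------
# Cohen's kappa
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    se: float | None
    ci95: tuple[float, float] | None


def cohens_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement for a 2x2 table.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe the
    chance agreement from the margins.  The standard error is the large-
    sample form of Fleiss, Cohen & Everitt (1969) and the CI is Wald.
    Degenerate margins (pe = 1) yield ``None`` fields.
    """
    n = cm.n
    p = np.array([[cm.tp, cm.fn], [cm.fp, cm.tn]], dtype=float) / n
    # p[i, j]: rater A assigns class i, rater B assigns class j, with
    # class order (positive, negative); diagonal = agreement.
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if abs(1.0 - pe) < 1e-12:
        return KappaResult(None, None, None)
    kappa = (po - pe) / (1.0 - pe)

    a = sum(p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
            for i in range(2))
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j)
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(0.975)
    return KappaResult(kappa, se, (kappa - z * se, kappa + z * se))


_KAPPA_BANDS = (
    (0.20, "slightly consistent"),
    (0.40, "fair consistent"),
    (0.60, "moderately consistent"),
    (0.80, "substantially consistent"),
    (1.00, "almost consistent"),
)


def kappa_band(kappa: float) -> str:
    """Qualitative interpretation band for a kappa value (six bands)."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.0:
        return "inconsistent"
    for upper, name in _KAPPA_BANDS:
        if kappa <= upper:
            return name
    raise AssertionError("unreachable")


# --------------------------------------------------------------------------
# intraclass correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    icc_single: float | None
    icc_average: float | None
    f_value: float | None
    df_between: int
    df_within: int


def icc_oneway(ratings: np.ndarray) -> IccResult:
    """One-way random-effects ICC for an items x raters table.

    F = MSB / MSW from the one-way ANOVA over items;
    single measures ICC(1) = (F - 1) / (F - 1 + k) and average measures
    ICC(1, k) = 1 - 1/F for k raters.  A table with zero variance yields
    ``None`` coefficients.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an items x raters table, >= 2 each")
    n, k = x.shape
    grand = x.mean()
    item_means = x.mean(axis=1)
    ss_between = k * float(((item_means - grand) ** 2).sum())
    ss_within = float(((x - item_means[:, None]) ** 2).sum())
    df_between = n - 1
    df_within = n * (k - 1)
    msb = ss_between / df_between
    msw = ss_within / df_within
    if msw == 0.0 and msb == 0.0:
        return IccResult(None, None, None, df_between, df_within)
    if msw == 0.0:
        return IccResult(1.0, 1.0, math.inf, df_between, df_within)
    f = msb / msw
    return IccResult((f - 1.0) / (f - 1.0 + k), 1.0 - 1.0 / f, f,
                     df_between, df_within)


def icc_average_from_f(f_value: float) -> float:
    """Average-measures one-way ICC implied by an ANOVA F value: 1 - 1/F."""
    if f_value <= 0:
        raise ValueError("F must be positive")
    return 1.0 - 1.0 / f_value


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se_auc: float
    n_pos: int
    n_neg: int


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be 0 (non-cancer) or 1 (cancer)")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley & McNeil (1982) standard error of a single empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC over the unique score thresholds.

    The trapezoidal AUC equals the Mann-Whitney statistic
    (concordant + ties/2) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_binary(labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores,
                                         drop_intermediate=False)
    auc = float(_trapezoid_auc(fpr, tpr))
    return RocCurve(fpr, tpr, thresholds, auc,
                    hanley_mcneil_se(auc, n_pos, n_neg), n_pos, n_neg)


@dataclass(frozen=True)
class PairedAucComparison:
    auc_a: float
    auc_b: float
    delta_auc: float
    se_delta: float | None
    z: float | None
    p_two_sided: float | None


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # structural, positives
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # structural, negatives
    return float(auc), v_pos, v_neg


def compare_auc_paired(scores_a, scores_b, labels) -> PairedAucComparison:
    """DeLong covariance-based test for two AUCs measured on the same items.

    z = (AUC_a - AUC_b) / SE(delta) with the paired DeLong variance; the
    p-value is two-sided normal.  If both scorers are identical the result
    is z = 0, p = 1; a degenerate non-zero delta (zero variance) yields
    ``None`` for z and p.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("scores and labels must share one shape")
    m, n = _check_binary(labels)
    auc_a, vp_a, vn_a = _delong_components(scores_a, labels)
    auc_b, vp_b, vn_b = _delong_components(scores_b, labels)
    delta = auc_a - auc_b

    def _cov(u: np.ndarray, v: np.ndarray) -> float:
        return float(((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1))

    var = ((_cov(vp_a, vp_a) + _cov(vp_b, vp_b) - 2 * _cov(vp_a, vp_b)) / m
           + (_cov(vn_a, vn_a) + _cov(vn_b, vn_b) - 2 * _cov(vn_a, vn_b)) / n)
    var = max(var, 0.0)
    if var == 0.0:
        if delta == 0.0:
            return PairedAucComparison(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0)
        return PairedAucComparison(auc_a, auc_b, delta, None, None, None)
    se = math.sqrt(var)
    z = delta / se
    p = 2.0 * float(norm.sf(abs(z)))
    return PairedAucComparison(auc_a, auc_b, delta, se, z, p)


def youden_optimal(roc: RocCurve) -> tuple[float, float]:
    """Youden-optimal operating point: J = max(tpr - fpr) over the curve's
    thresholds; ties break toward the higher cutoff."""
    j = roc.tpr - roc.fpr
    best = float(j.max())
    cutoffs = roc.thresholds[j == best]
    return float(cutoffs.max()), best


# --------------------------------------------------------------------------
# dataset split
# --------------------------------------------------------------------------

def split_dataset(n_items: int, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform split: floor(train_fraction * n) items to training,
    the remainder to validation; disjoint and exhaustive."""
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in [0, 1]")
    n_train = int(math.floor(train_fraction * n_items))
    perm = np.random.default_rng(seed).permutation(n_items)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
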