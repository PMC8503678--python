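"""Integer confusion-matrix reconstruction from printed summary rows.

Published screening studies usually print only (N, sensitivity, specificity,
accuracy) per rater, rounded to a few decimals.  Because all four quantities
are ratios of integers, the underlying 2x2 confusion matrix is tightly
constrained: this module enumerates every integer matrix consistent with the
printed row (exact integer arithmetic over the half-open rounding
intervals), derives the implied ranges of PPV, NPV and Cohen's kappa, and
picks a deterministic central representative by solving
``accuracy = sens * p + spec * (1 - p)`` for the prevalence ``p``.  Printed
companion values can then be audited against the implied values at
rounding-propagation tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .stats import ConfusionMatrix, cohens_kappa, confusion_metrics

KAPPA_TOLERANCE = 0.01
RATE_TOLERANCE = 0.005


@dataclass(frozen=True)
class SummaryRow:
    """One printed row: counts plus rates rounded to ``dp`` decimals.

    ``positives`` optionally pins the positive count P = TP + FN when the
    row alone cannot identify it (e.g. a degenerate all-perfect row).
    """

    label: str
    n: int
    sens: float
    spec: float
    acc: float
    ppv: float | None = None
    npv: float | None = None
    kappa: float | None = None
    dp: int = 3
    positives: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name in ("sens", "spec", "acc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dp < 1:
            raise ValueError("dp must be >= 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _int_range_for_rate(den: int, rate: float, dp: int) -> range:
    """Integers k with round_half_up(k / den, dp) == rate, as exact integer
    bounds: k / den in [rate - h, rate + h) with h = 0.5 * 10^-dp, i.e.
    2 * 10^dp * k in [den * (2R - 1), den * (2R + 1)) where R = rate * 10^dp.
    """
    scale = 10 ** dp
    r_scaled = _round_half_up(rate * scale)  # printed value as an integer
    lo_num = den * (2 * r_scaled - 1)
    hi_num = den * (2 * r_scaled + 1)
    lo = -(-lo_num // (2 * scale))          # ceil
    hi = -(-hi_num // (2 * scale)) - 1      # last k with 2*scale*k < hi_num
    if 2 * scale * hi == hi_num:            # half-open: exclude the top edge
        hi -= 1
    lo = max(lo, 0)
    hi = min(hi, den)
    return range(lo, hi + 1)


@dataclass
class FeasibleSet:
    """All integer confusion matrices consistent with a printed row."""

    row: SummaryRow
    counts: np.ndarray  # (n_solutions, 4) columns tp, fp, fn, tn
    central: ConfusionMatrix | None
    consistent: bool = True
    indeterminate_prevalence: bool = False
    kappa_range: tuple[float, float] | None = field(default=None)
    ppv_range: tuple[float, float] | None = field(default=None)
    npv_range: tuple[float, float] | None = field(default=None)

    @property
    def n_solutions(self) -> int:
        return len(self.counts)

    def matrices(self) -> list[ConfusionMatrix]:
        return [ConfusionMatrix(*map(int, r)) for r in self.counts]


def _kappa_many(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray,
                tn: np.ndarray) -> np.ndarray:
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.isclose(pe, 1.0), np.nan, (po - pe) / (1.0 - pe))


def central_solution(row: SummaryRow) -> ConfusionMatrix | None:
    """Deterministic representative: real-valued prevalence rounded to
    integer counts.  ``None`` when sens == spec and no positive count is
    pinned (the prevalence is then unidentified)."""
    if row.positives is not None:
        p_count = row.positives
    elif row.sens == row.spec:
        return None
    else:
        prevalence = (row.acc - row.spec) / (row.sens - row.spec)
        p_count = _round_half_up(row.n * prevalence)
    p_count = min(max(p_count, 0), row.n)
    tp = _round_half_up(row.sens * p_count)
    tn = _round_half_up(row.spec * (row.n - p_count))
    return ConfusionMatrix(tp=tp, fp=row.n - p_count - tn,
                           fn=p_count - tp, tn=tn)


def enumerate_feasible(row: SummaryRow) -> FeasibleSet:
    """Exhaustively enumerate integer matrices reproducing the printed
    sensitivity, specificity and accuracy after rounding to ``dp`` decimals.

    An empty set marks the row as inconsistent (no exception); a row whose
    every prevalence is feasible is flagged ``indeterminate_prevalence``.
    """
    scale = 10 ** row.dp
    acc_scaled = _round_half_up(row.acc * scale)
    acc_lo = row.n * (2 * acc_scaled - 1)   # bounds on 2*scale*(tp+tn)
    acc_hi = row.n * (2 * acc_scaled + 1)
    sols: list[tuple[int, int, int, int]] = []
    p_values = ([row.positives] if row.positives is not None
                else range(1, row.n))
    for p_count in p_values:
        neg = row.n - p_count
        if p_count <= 0 or neg <= 0:
            continue
        for tp in _int_range_for_rate(p_count, row.sens, row.dp):
            for tn in _int_range_for_rate(neg, row.spec, row.dp):
                s = 2 * scale * (tp + tn)
                if acc_lo <= s < acc_hi:
                    sols.append((tp, neg - tn, p_count - tp, tn))
    counts = np.array(sols, dtype=np.int64).reshape(-1, 4)
    if len(counts) == 0:
        return FeasibleSet(row, counts, central_solution(row),
                           consistent=False)

    distinct_p = np.unique(counts[:, 0] + counts[:, 2])
    indeterminate = (row.positives is None
                     and len(distinct_p) == row.n - 1)
    tp, fp, fn, tn = (counts[:, i].astype(float) for i in range(4))
    kappas = _kappa_many(tp, fp, fn, tn)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        npv = np.where(tn + fn > 0, tn / (tn + fn), np.nan)

    def _span(v: np.ndarray) -> tuple[float, float] | None:
        v = v[~np.isnan(v)]
        return (float(v.min()), float(v.max())) if v.size else None

    return FeasibleSet(row, counts, central_solution(row), consistent=True,
                       indeterminate_prevalence=indeterminate,
                       kappa_range=_span(kappas), ppv_range=_span(ppv),
                       npv_range=_span(npv))


def implied_kappa(row: SummaryRow) -> tuple[float, tuple[float, float]]:
    """Central kappa plus the (min, max) range over every feasible matrix."""
    fs = enumerate_feasible(row)
    if not fs.consistent:
        raise ValueError(f"row {row.label!r} is inconsistent: "
                         "no integer matrix reproduces the printed rates")
    if fs.central is None:
        raise ValueError(f"row {row.label!r} has unidentified prevalence; "
                         "supply positives=")
    central = cohens_kappa(fs.central).kappa
    return float(central), fs.kappa_range


@dataclass
class RowAudit:
    label: str
    consistent: bool
    indeterminate_prevalence: bool
    n_solutions: int
    central_counts: tuple[int, int, int, int] | None
    implied: dict
    printed: dict
    deltas: dict
    flags: list[str]


@dataclass
class AuditReport:
    entries: list[RowAudit]

    def to_json(self) -> str:
        return json.dumps([e.__dict__ for e in self.entries], sort_keys=True,
                          default=str)

    def to_text(self) -> str:
        lines = []
        for e in self.entries:
            status = "ok" if e.consistent and not e.flags else \
                ("INCONSISTENT" if not e.consistent else
                 "FLAGGED: " + ", ".join(e.flags))
            lines.append(f"{e.label}: {status} "
                         f"({e.n_solutions} feasible matrices)")
            for key, delta in e.deltas.items():
                lines.append(f"  {key}: printed {e.printed[key]} "
                             f"implied {e.implied[key]:.4f} "
                             f"delta {delta:+.4f}")
        return "\n".join(lines)


def audit_tables(rows: list[SummaryRow]) -> AuditReport:
    """Audit printed PPV/NPV/kappa values against the reconstruction.

    Deltas beyond the rounding-propagation tolerances (0.01 for kappa,
    0.005 for PPV/NPV) are flagged, as are rows with an empty feasible set.
    """
    entries = []
    for row in rows:
        fs = enumerate_feasible(row)
        implied: dict = {}
        printed: dict = {}
        deltas: dict = {}
        flags: list[str] = []
        if not fs.consistent:
            flags.append("no feasible confusion matrix")
        central = fs.central
        if central is not None and fs.consistent:
            metrics = confusion_metrics(central)
            kr = cohens_kappa(central)
            cand = {"ppv": (row.ppv, metrics.ppv, RATE_TOLERANCE),
                    "npv": (row.npv, metrics.npv, RATE_TOLERANCE),
                    "kappa": (row.kappa, kr.kappa, KAPPA_TOLERANCE)}
            for key, (printed_v, implied_v, tol) in cand.items():
                if printed_v is None or implied_v is None:
                    continue
                printed[key] = printed_v
                implied[key] = implied_v
                deltas[key] = printed_v - implied_v
                if abs(deltas[key]) > tol:
                    flags.append(f"{key} beyond tolerance {tol}")
        entries.append(RowAudit(
            label=row.label,
            consistent=fs.consistent,
            indeterminate_prevalence=fs.indeterminate_prevalence,
            n_solutions=fs.n_solutions,
            central_counts=(None if central is None else
                            (central.tp, central.fp, central.fn, central.tn)),
            implied=implied, printed=printed, deltas=deltas, flags=flags,
        ))
    return AuditReport(entries)
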