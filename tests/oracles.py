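"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most literal method available
(flood fill, exhaustive enumeration, naive sweeps) without touching the
implementation path it is checking.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    H, W = mask.shape
    for sr in range(H):
        for sc in range(W):
            if not mask[sr, sc] or labels[sr, sc]:
                continue
            current += 1
            queue = deque([(sr, sc)])
            labels[sr, sc] = current
            while queue:
                r, c = queue.popleft()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < H and 0 <= cc < W and mask[rr, cc]
                                and not labels[rr, cc]):
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels


def pairwise_auc(scores, labels) -> float:
    """AUC as (concordant + ties/2) / (n_pos * n_neg) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def min_rect_by_edge_sweep(coords: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area bounding rectangle by sweeping every convex-hull edge
    direction of the pixel-corner point set.  Returns (area, w, h) with
    w <= h."""
    from scipy.spatial import ConvexHull

    coords = np.asarray(coords, dtype=float)
    offsets = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    corners = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    hull_pts = corners[ConvexHull(corners).vertices]
    best = (np.inf, 0.0, 0.0)
    n = len(hull_pts)
    for i in range(n):
        edge = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        u = edge / norm
        v = np.array([-u[1], u[0]])
        a = hull_pts @ u
        b = hull_pts @ v
        w = a.max() - a.min()
        h = b.max() - b.min()
        if w * h < best[0]:
            best = (w * h, min(w, h), max(w, h))
    return best


def otsu_naive(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold by naive scan of every histogram split point."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_var = centers[0], -1.0
    total = hist.sum()
    for i in range(1, nbins):
        w0 = hist[:i].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:i] * centers[:i]).sum() / w0
        mu1 = (hist[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = centers[i - 1]
    return float(best_t)


def anova_icc(table: np.ndarray) -> tuple[float, float, float]:
    """One-way ICCs by explicit ANOVA sums: (icc_single, icc_average, F)."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msb = sum(k * (row.mean() - grand) ** 2 for row in x) / (n - 1)
    msw = sum((v - row.mean()) ** 2 for row in x for v in row) / (n * (k - 1))
    f = msb / msw
    return (msb - msw) / (msb + (k - 1) * msw), (msb - msw) / msb, f


def youden_scan(scores, labels) -> tuple[float, float]:
    """Exhaustive Youden scan: J over every cutoff (call = score >= cutoff),
    ties broken toward the higher cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_j, best_cut = -np.inf, None
    for cut in sorted(set(scores)) + [np.inf]:
        calls = scores >= cut
        tpr = (calls & (labels == 1)).sum() / n_pos
        fpr = (calls & (labels == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j or (j == best_j and cut > best_cut):
            best_j, best_cut = j, cut
    return best_cut, float(best_j)


def feasible_bruteforce(n: int, sens: float, spec: float, acc: float,
                        dp: int = 3) -> set[tuple[int, int, int, int]]:
    """All (tp, fp, fn, tn) summing to n whose rates round (half-up) to the
    printed values; full scan, practical for n <= ~200."""
    def _rounds_to(num: int, den: int, target: float) -> bool:
        if den == 0:
            return False
        scale = 10 ** dp
        return int(np.floor(num / den * scale + 0.5)) == int(
            np.floor(target * scale + 0.5))

    out = set()
    for p in range(1, n):
        neg = n - p
        for tp in range(p + 1):
            if not _rounds_to(tp, p, sens):
                continue
            for tn in range(neg + 1):
                if not _rounds_to(tn, neg, spec):
                    continue
                if _rounds_to(tp + tn, n, acc):
                    out.add((tp, neg - tn, p - tp, tn))
    return out


def bootstrap_se_delta_auc(scores_a, scores_b, labels, n_boot: int = 10_000,
                           seed: int = 0) -> float:
    """Bootstrap standard error of AUC_a - AUC_b under paired resampling,
    stratified by class."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        pi = pos[rng.integers(0, len(pos), len(pos))]
        ni = neg[rng.integers(0, len(neg), len(neg))]
        deltas[b] = (_pair_auc(scores_a, pi, ni)
                     - _pair_auc(scores_b, pi, ni))
    return float(deltas.std(ddof=1))


def _pair_auc(scores: np.ndarray, pos_idx: np.ndarray,
              neg_idx: np.ndarray) -> float:
    diff = scores[pos_idx][:, None] - scores[neg_idx][None, :]
    return (np.count_nonzero(diff > 0)
            + 0.5 * np.count_nonzero(diff == 0)) / diff.size
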