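"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (BFS flood fill, all-pairs scans,
exhaustive enumeration) and shares no code with the package internals.
"""

import itertools

import numpy as np
from scipy.stats import norm


def flood_fill_patches(year_grid):
    """Queen-contiguity components per year via BFS; returns list of
    (year, frozenset of (r, c)) sorted by (year, first pixel)."""
    nrows, ncols = year_grid.shape
    seen = np.zeros_like(year_grid, dtype=bool)
    comps = []
    for r in range(nrows):
        for c in range(ncols):
            if year_grid[r, c] == 0 or seen[r, c]:
                continue
            year = year_grid[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            comp = []
            while stack:
                rr, cc = stack.pop()
                comp.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < nrows
                            and 0 <= c2 < ncols
                            and not seen[r2, c2]
                            and year_grid[r2, c2] == year
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            comps.append((int(year), frozenset(comp)))
    comps.sort(key=lambda t: (t[0], min(t[1])))
    return comps


def brute_merge(comps, year_grid):
    """Merge components of consecutive years sharing a 4-adjacent pixel pair,
    by exhaustive pixel-pair enumeration and union-find; merged year is the
    modal pixel year (ties to the earlier year)."""
    n = len(comps)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i, j in itertools.combinations(range(n), 2):
        yi, pi = comps[i]
        yj, pj = comps[j]
        if abs(yi - yj) != 1:
            continue
        hit = any(
            abs(r1 - r2) + abs(c1 - c2) == 1 for r1, c1 in pi for r2, c2 in pj
        )
        if hit:
            union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        pixels = frozenset().union(*(comps[i][1] for i in members))
        years = [year_grid[r, c] for r, c in pixels]
        vals, counts = np.unique(years, return_counts=True)
        year = int(vals[np.flatnonzero(counts == counts.max())[0]])
        merged.append((year, pixels))
    merged.sort(key=lambda t: (t[0], min(t[1])))
    return merged


def pairwise_context(centroids_xy, years, areas, radius, t_window):
    """All-pairs landscape context: (count, summed area, nn distance)."""
    n = len(years)
    out = []
    for i in range(n):
        cnt, area, nn = 0, 0.0, float(radius)
        for j in range(n):
            if j == i or abs(years[j] - years[i]) > t_window:
                continue
            d = float(np.hypot(centroids_xy[j, 0] - centroids_xy[i, 0],
                               centroids_xy[j, 1] - centroids_xy[i, 1]))
            if d <= radius:
                cnt += 1
                area += areas[j]
                nn = min(nn, d)
        out.append((cnt, area, nn))
    return out


def concordance_auc(labels, scores):
    """AUC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def trapezoid_auc(labels, scores):
    """ROC area by trapezoidal integration of the empirical ROC curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def exhaustive_f1_cutoff(probs, labels):
    """Best achievable F1 over all thresholds induced by distinct scores."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    best = 0.0
    candidates = np.concatenate([np.unique(probs), [np.inf]])
    for c in candidates:
        pred = probs >= c
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int(((~pred) & (labels == 1)).sum())
        if 2 * tp + fp + fn > 0:
            best = max(best, 2 * tp / (2 * tp + fp + fn))
    return best


def exhaustive_vdw_p(x1, x2):
    """Two-sided exhaustive-permutation Van der Waerden p-value."""
    pooled = np.concatenate([np.asarray(x1, float), np.asarray(x2, float)])
    N = len(pooled)
    n2 = len(x2)
    order = pooled.argsort().argsort() + 1.0  # ranks, no ties assumed
    scores = norm.ppf(order / (N + 1))
    obs = abs(scores[-n2:].sum() - n2 * scores.mean())
    count = total = 0
    for idx in itertools.combinations(range(N), n2):
        t = scores[list(idx)].sum()
        total += 1
        if abs(t - n2 * scores.mean()) >= obs - 1e-12:
            count += 1
    return count / total
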