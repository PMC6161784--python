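"""Independent brute-force and closed-form oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, textbook formulas) and shares no code with the implementation
it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import multivariate_normal, norm

ALL_26_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

AXIS_6_OFFSETS = [o for o in ALL_26_OFFSETS if sum(abs(c) for c in o) == 1]


def brute_nglcm(grid_levels: np.ndarray, ng: int, distance: int = 1):
    """Ordered-pair enumeration over all 26 neighbors of every voxel."""
    counts = np.zeros((ng, ng))
    nx, ny, nz = grid_levels.shape
    for x, y, z in product(range(nx), range(ny), range(nz)):
        a = grid_levels[x, y, z]
        if a <= 0:
            continue
        for dx, dy, dz in ALL_26_OFFSETS:
            px, py, pz = x + distance * dx, y + distance * dy, z + distance * dz
            if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz:
                b = grid_levels[px, py, pz]
                if b > 0:
                    counts[a - 1, b - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total, int(total)


def brute_size_variation(grid_levels: np.ndarray, connectivity: int = 26) -> float:
    """Loop over voxels; mean |level - mean(in-mask neighbor levels)|."""
    offsets = ALL_26_OFFSETS if connectivity == 26 else AXIS_6_OFFSETS
    nx, ny, nz = grid_levels.shape
    diffs = []
    for x, y, z in product(range(nx), range(ny), range(nz)):
        a = grid_levels[x, y, z]
        if a <= 0:
            continue
        nbrs = []
        for dx, dy, dz in offsets:
            px, py, pz = x + dx, y + dy, z + dz
            if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz:
                b = grid_levels[px, py, pz]
                if b > 0:
                    nbrs.append(b)
        if nbrs:
            diffs.append(abs(a - float(np.mean(nbrs))))
    if not diffs:
        raise ValueError("no voxel with a neighbor")
    return float(np.mean(diffs))


def brute_auc(scores, labels) -> float:
    """All positive-negative pairs; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_youden(scores, labels):
    """Exhaustive threshold/direction scan replicating the documented rule.

    Direction so AUC >= 0.5; thresholds are midpoints between adjacent
    distinct scores plus +/-inf; ties in J broken toward smallest |cutoff|.
    Returns (direction, cutoff, J, sensitivity, specificity).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    auc = brute_auc(scores, labels)
    direction = "greater" if auc >= 0.5 else "less_equal"
    uniq = np.unique(scores)
    mids = [(uniq[i] + uniq[i + 1]) / 2.0 for i in range(len(uniq) - 1)]
    n_pos, n_neg = labels.sum(), (~labels).sum()
    best = None
    for t in [-np.inf, *mids, np.inf]:
        if direction == "greater":
            pred = scores > t
            cutoff = t
        else:
            pred = scores <= t
            cutoff = t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        key = (-round(j, 12), abs(cutoff), cutoff)
        if best is None or key < best[0]:
            best = (key, cutoff, j, sens, spec)
    _, cutoff, j, sens, spec = best
    return direction, float(cutoff), float(j), float(sens), float(spec)


def brute_spearman(x, y) -> float:
    """Average-rank assignment by hand, then Pearson on the ranks."""

    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def copula_auc_theory(rho_s: float, responder_fraction: float) -> float:
    """Closed-form AUC of an h-monotone score for the non-responder class.

    Under the Gaussian copula, the latent h and the delta's Gaussian driver z
    are bivariate normal with Pearson r = 2 sin(pi rho_s / 6); non-response
    is z > c with c = Phi^{-1}(responder fraction). The AUC
    P(h_pos > h_neg | z_pos > c, z_neg < c) is a trivariate-normal orthant
    probability evaluated with scipy's MVN cdf.
    """
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    c = norm.ppf(responder_fraction)
    # X = (-(h1-h0), -z1, z0): AUC numerator = P(X < (0, -c, c))
    cov = np.array([[2.0, r, r], [r, 1.0, 0.0], [r, 0.0, 1.0]])
    num = multivariate_normal(mean=np.zeros(3), cov=cov).cdf(np.array([0.0, -c, c]))
    denom = (1.0 - norm.cdf(c)) * norm.cdf(c)
    return float(num / denom)
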