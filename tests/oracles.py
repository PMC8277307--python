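"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the definitions, with explicit
loops and no reuse of the code paths under test.
"""

from __future__ import annotations

import math

import numpy as np


def silhouette_brute(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette by full pairwise enumeration.

    Per point: a = mean distance to other members of its own cluster,
    b = smallest mean distance to the members of any other cluster,
    s = (b - a) / max(a, b); singleton clusters score 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    ids = np.unique(labels)
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = sum(math.dist(points[i], points[j]) for j in own) / len(own)
        b = math.inf
        for c in ids:
            if c == labels[i]:
                continue
            others = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(math.dist(points[i], points[j]) for j in others) / len(others))
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def radius_brute(points: np.ndarray, centroid: np.ndarray) -> float:
    """Mean point-to-centroid Euclidean distance by direct loop."""
    centroid = np.asarray(centroid, dtype=float)
    return float(np.mean([math.dist(p, centroid) for p in np.asarray(points, dtype=float)]))


def kappa_brute(codes_a: list, codes_b: list) -> float:
    """Cohen kappa computed from raw paired codes by counting."""
    n = len(codes_a)
    p_o = sum(a == b for a, b in zip(codes_a, codes_b)) / n
    cats = sorted(set(codes_a) | set(codes_b))
    p_e = sum(
        (codes_a.count(c) / n) * (codes_b.count(c) / n) for c in cats
    )
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def pooled_t_brute(a: list[float], b: list[float]) -> tuple[float, float]:
    """Pooled two-sample t statistic and df from the textbook formula."""
    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def summary_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> tuple[float, float]:
    """Pooled t from group summary statistics (means, SDs, sizes)."""
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    t = (mean_a - mean_b) / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
    return t, n_a + n_b - 2


def l1_logistic_brute(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Fit binary l1-penalized logistic regression by gradient-free search.

    Minimizes ||w||_1 + |b| + C * sum_i log(1 + exp(-s_i (w.x_i + b)))
    with s_i = 2 y_i - 1 (the intercept enters the penalty the same way
    the augmented-feature formulation penalizes it).  Returns [w, b].
    """
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    s = 2.0 * np.asarray(y, dtype=float) - 1.0

    def objective(wb):
        z = X @ wb[:-1] + wb[-1]
        return np.abs(wb).sum() + C * np.logaddexp(0.0, -s * z).sum()

    best = None
    for start_scale in (0.0, 0.5, -0.5):
        x0 = np.full(X.shape[1] + 1, start_scale)
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x
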