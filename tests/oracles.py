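"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and where practical the
libraries) they validate: flood-fill labeling by explicit BFS, Otsu by
exhaustive threshold search, OLS by the normal equations, quartiles by
hand-rolled order-statistic interpolation, and logistic ML by iterative
grid refinement.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import stats as sps


def largest_component_fill_oracle(mask: np.ndarray) -> np.ndarray:
    """BFS flood fill: label 8-connected components, keep the largest
    (ties: smallest row-major first index), then fill any background not
    4-connected to the image border."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = -np.ones((h, w), dtype=int)
    comps: list[list[tuple[int, int]]] = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] < 0:
                comp = []
                q = deque([(i, j)])
                labels[i, j] = len(comps)
                while q:
                    y, x = q.popleft()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < h and 0 <= nx < w
                                and mask[ny, nx] and labels[ny, nx] < 0
                            ):
                                labels[ny, nx] = len(comps)
                                q.append((ny, nx))
                comps.append(comp)
    if not comps:
        raise ValueError("empty mask")
    best = max(range(len(comps)),
               key=lambda k: (len(comps[k]), -min(y * w + x for y, x in comps[k])))
    keep = np.zeros((h, w), dtype=bool)
    for y, x in comps[best]:
        keep[y, x] = True

    # background reachable from the border, 4-connectivity
    outside = np.zeros((h, w), dtype=bool)
    q = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not keep[i, j] and not outside[i, j]:
                outside[i, j] = True
                q.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not keep[i, j] and not outside[i, j]:
                outside[i, j] = True
                q.append((i, j))
    while q:
        y, x = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not keep[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                q.append((ny, nx))
    return keep | ~outside


def otsu_oracle(image: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over histogram bins."""
    img = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(img, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_thr, best_var = centers[0], -1.0
    total = counts.sum()
    for k in range(1, n_bins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, edges[k]
    return float(best_thr)


def ols_oracle(y: np.ndarray, X: np.ndarray):
    """Normal-equations OLS with classical t-test p-values and R^2."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = n - p
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * sps.t.sf(np.abs(t), dof)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / ss_tot
    return beta, se, pvals, r2


def quartiles_oracle(x: np.ndarray) -> tuple[float, float]:
    """Q1/Q3 by linear interpolation of sorted order statistics."""
    s = np.sort(np.asarray(x, dtype=float))
    n = len(s)

    def quantile(q: float) -> float:
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    return quantile(0.25), quantile(0.75)


def tukey_outliers_oracle(x: np.ndarray) -> np.ndarray:
    q1, q3 = quartiles_oracle(x)
    iqr = q3 - q1
    x = np.asarray(x, dtype=float)
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def logit_grid_oracle(y: np.ndarray, X: np.ndarray, span: float = 6.0,
                      n_iter: int = 30, n_pts: int = 7) -> np.ndarray:
    """Maximum-likelihood logit coefficients by iterative grid refinement.

    Searches a shrinking hypercube around the running best point; with 30
    halvings the final resolution is far below 1e-3 per coefficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    center = np.zeros(p)
    width = span
    for _ in range(n_iter):
        axes = [np.linspace(c - width, c + width, n_pts) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)      # (n_pts^p, p)
        eta = cand @ X.T                                          # (m, n)
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        center = cand[np.argmax(ll)]
        width *= 0.55
    return center
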