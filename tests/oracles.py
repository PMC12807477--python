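"""Independent brute-force reference implementations used as test oracles.

Every function here re-derives a statistic by a route independent of the
package's implementation (direct likelihood evaluation, explicit loops,
naive agglomeration), so agreement is evidence of correctness rather
than of shared code.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sps


def g_test_binomial_loglik(c_ip: int, c_igg: int, t_ip: int, t_igg: int
                           ) -> tuple[float, float]:
    """G statistic via binomial log-pmf evaluation (not the closed form).

    The spectral-count G test is the LRT of the binomial proportion
    c_ip/(c_ip+c_igg) against the fixed depth ratio T_ip/(T_ip+T_igg).
    """
    n = c_ip + c_igg
    if n == 0:
        return 0.0, 1.0
    p_hat = c_ip / n
    p0 = t_ip / (t_ip + t_igg)
    g = 2.0 * (sps.binom.logpmf(c_ip, n, p_hat) - sps.binom.logpmf(c_ip, n, p0))
    g = max(float(g), 0.0)
    return g, float(sps.chi2.sf(g, df=1))


def welch_t_formula(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t and two-sided p from the textbook formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = len(a), len(b)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def paired_t_formula(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed t from the difference-vector formula."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values by the explicit step-up definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = running_min
    return q


def binomial_lrt_loglik(i1, s1, i2, s2) -> tuple[float, float]:
    """Pooled-group binomial LRT via log-pmf evaluation at the MLEs."""
    n1, n2 = i1 + s1, i2 + s2
    p1, p2 = i1 / n1, i2 / n2
    p0 = (i1 + i2) / (n1 + n2)
    ll1 = sps.binom.logpmf(i1, n1, p1) + sps.binom.logpmf(i2, n2, p2)
    ll0 = sps.binom.logpmf(i1, n1, p0) + sps.binom.logpmf(i2, n2, p0)
    g = max(float(2.0 * (ll1 - ll0)), 0.0)
    return g, float(sps.chi2.sf(g, df=1))


def gsea_running_sum_loop(metric_sorted: np.ndarray, member: np.ndarray,
                          weight: float = 1.0) -> float:
    """Weighted KS enrichment score by an explicit element loop."""
    n = len(metric_sorted)
    n_hit = int(member.sum())
    w = np.abs(metric_sorted) ** weight
    denom = float(np.sum(w[member]))
    hit = miss = 0.0
    best = 0.0
    for i in range(n):
        if member[i]:
            hit += w[i] / denom
        else:
            miss += 1.0 / (n - n_hit)
        if abs(hit - miss) > abs(best):
            best = hit - miss
    return best


def upgma_merge_heights(dist: np.ndarray) -> list[float]:
    """Average-linkage (UPGMA) agglomeration by a naive O(n^3) loop.

    Returns the sorted merge heights; cluster-to-cluster distance is the
    size-weighted mean of the original pairwise distances.
    """
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


def feret_all_points(coords: np.ndarray, step_deg: float = 1.0
                     ) -> tuple[float, float]:
    """Feret diameters by projecting ALL pixel coordinates (no hull)."""
    pts = np.asarray(coords, float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    widths = []
    for th in angles:
        proj = pts[:, 0] * np.cos(th) + pts[:, 1] * np.sin(th)
        widths.append(proj.max() - proj.min())
    widths = np.asarray(widths)
    return float(widths.min()), float(widths.max())
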