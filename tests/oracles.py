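"""Independent oracles used by the test suite.

These deliberately take different computational routes from the package:
fine-grid least-squares search instead of iterative curve fitting,
exhaustive permutation enumeration instead of Monte-Carlo sampling, and
literal sums-of-squares loops instead of vectorised ANOVA algebra.
"""

from __future__ import annotations

import itertools

import numpy as np


# ----------------------------------------------------------------------
# spectral parameterization: fine-grid least squares

def grid_fit_single_peak(freqs: np.ndarray, log_power: np.ndarray,
                         cf_window: tuple[float, float],
                         sd_window: tuple[float, float],
                         cf_step: float = 0.02, sd_step: float = 0.05):
    """Best (offset, exponent, cf, height, sd) by exhaustive grid search.

    For every candidate (cf, sd) on a fine grid the remaining parameters
    (offset, exponent, height) enter linearly and are solved by least
    squares; the SSE-minimising candidate wins.
    """
    log_f = np.log10(freqs)
    cfs = np.arange(cf_window[0], cf_window[1] + 1e-9, cf_step)
    sds = np.arange(max(sd_window[0], 0.2), sd_window[1] + 1e-9, sd_step)
    best = None
    ones = np.ones_like(freqs)
    for cf in cfs:
        d = freqs - cf
        for sd in sds:
            g = np.exp(-0.5 * (d / sd) ** 2)
            X = np.column_stack([ones, -log_f, g])
            beta, _, _, _ = np.linalg.lstsq(X, log_power, rcond=None)
            sse = float(np.sum((log_power - X @ beta) ** 2))
            if best is None or sse < best[0]:
                best = (sse, float(beta[0]), float(beta[1]), float(cf),
                        float(beta[2]), float(sd))
    sse, offset, exponent, cf, height, sd = best
    return {"sse": sse, "offset": offset, "exponent": exponent,
            "cf": cf, "height": height, "sd": sd}


# ----------------------------------------------------------------------
# cluster permutation: exhaustive enumeration for 2 conditions

def _rm_f_map(data: np.ndarray) -> np.ndarray:
    """Loop-based repeated-measures F at every point; data (P, C, n_points)."""
    p, c, npts = data.shape
    out = np.zeros(npts)
    for j in range(npts):
        y = data[:, :, j]
        grand = y.mean()
        ss_cond = p * sum((y[:, k].mean() - grand) ** 2 for k in range(c))
        ss_err = 0.0
        for i in range(p):
            for k in range(c):
                ss_err += (y[i, k] - y[:, k].mean() - y[i].mean() + grand) ** 2
        df1, df2 = c - 1, (c - 1) * (p - 1)
        out[j] = (ss_cond / df1) / (ss_err / df2) if ss_err > 0 else 0.0
    return out


def _bfs_clusters(supra: np.ndarray, stat: np.ndarray, neighbours) -> list[float]:
    """Cluster sums via breadth-first search over an explicit neighbour map."""
    seen = set()
    sums = []
    for start in np.flatnonzero(supra):
        if start in seen:
            continue
        queue, total = [int(start)], 0.0
        seen.add(int(start))
        while queue:
            v = queue.pop()
            total += stat[v]
            for w in neighbours[v]:
                if supra[w] and w not in seen:
                    seen.add(w)
                    queue.append(w)
        sums.append(total)
    return sums


def exhaustive_two_condition_cluster_p(data: np.ndarray, crit: float,
                                       neighbours) -> float:
    """Exact p of the max cluster sum over all 2^P condition swaps.

    ``data`` is participants x 2 x n_points; ``neighbours`` maps point
    index -> iterable of neighbouring point indices.
    """
    p = data.shape[0]

    def max_cluster(d):
        f = _rm_f_map(d)
        sums = _bfs_clusters(f > crit, f, neighbours)
        return max(sums, default=0.0)

    observed = max_cluster(data)
    count = 0
    total = 0
    for swaps in itertools.product([0, 1], repeat=p):
        d = data.copy()
        for i, s in enumerate(swaps):
            if s:
                d[i] = d[i, ::-1]
        total += 1
        if max_cluster(d) >= observed - 1e-12:
            count += 1
    return count / total


# ----------------------------------------------------------------------
# repeated-measures ANOVA: literal definitional loops

def brute_force_oneway_rm(data: np.ndarray) -> dict:
    """SS, df and F for a one-way within design, computed by explicit loops."""
    n, k = data.shape
    grand = data.mean()
    level_means = [data[:, j].mean() for j in range(k)]
    subj_means = [data[i].mean() for i in range(n)]
    ss_effect = n * sum((m - grand) ** 2 for m in level_means)
    ss_error = 0.0
    for i in range(n):
        for j in range(k):
            ss_error += (data[i, j] - level_means[j] - subj_means[i] + grand) ** 2
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_effect / df1) / (ss_error / df2)
    return {"ss": ss_effect, "ss_error": ss_error, "df1": df1, "df2": df2, "F": f}
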