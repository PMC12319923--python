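"""Cluster-based permutation tests over channel x frequency (x time) grids.

Point-wise dependent-samples statistics (repeated-measures F across
conditions, or one-sample t of participant effects against zero) are
thresholded, supra-threshold points are grouped into clusters via spatial
channel adjacency plus immediate frequency/time grid neighbourhood, and each
cluster's summed statistic is compared against a max-statistic Monte-Carlo
null built by permuting condition labels within participants (F) or flipping
participant signs (t). Clusters must contain at least ``min_channels``
distinct channels that are adjacency neighbours at an overlapping
frequency/time point.

Monte-Carlo p-values are +1-corrected:
``p = (1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .layouts import ChannelLayout

__all__ = ["AdjacencyGraph", "ClusterResult", "build_adjacency",
           "cluster_permutation_test"]

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyGraph:
    names: list[str]
    matrix: np.ndarray  # boolean, symmetric, irreflexive

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.names):
            raise ValueError("adjacency must be square and match names")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(m, False)
        self.matrix = m

    @property
    def mean_degree(self) -> float:
        return float(self.matrix.sum(axis=1).mean())


def build_adjacency(layout: ChannelLayout, method: str = "delaunay",
                    threshold: float | None = None,
                    k: int = 4) -> AdjacencyGraph:
    """Neighbour structure from 2-D sensor positions.

    ``delaunay`` triangulates the layout and prunes edges longer than
    ``threshold`` (default 1.6 x the median Delaunay edge length), which for
    the standard 32-channel cap yields a mean degree close to the template
    value of 6 neighbours per electrode. Degenerate (collinear) layouts fall
    back to mutual k-nearest neighbours.
    """
    n = len(layout)
    if n < 2:
        raise ValueError("need at least 2 channels")
    pos = layout.pos
    adj = np.zeros((n, n), dtype=bool)

    if n == 2:
        d = np.linalg.norm(pos[0] - pos[1])
        if threshold is None or d <= threshold:
            adj[0, 1] = adj[1, 0] = True
        return AdjacencyGraph(names=layout.names, matrix=adj)

    if method == "knn":
        return _knn_adjacency(layout, k)
    if method != "delaunay":
        raise ValueError(f"unknown method {method!r}")

    from scipy.spatial import Delaunay, QhullError
    try:
        tri = Delaunay(pos)
    except QhullError:
        logger.warning("degenerate layout; falling back to k-nearest neighbours")
        return _knn_adjacency(layout, k)

    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                edges.add((min(simplex[a], simplex[b]), max(simplex[a], simplex[b])))
    lengths = {e: np.linalg.norm(pos[e[0]] - pos[e[1]]) for e in edges}
    if threshold is None:
        threshold = 1.6 * float(np.median(list(lengths.values())))
    for (a, b), d in lengths.items():
        if d <= threshold:
            adj[a, b] = adj[b, a] = True
    graph = AdjacencyGraph(names=layout.names, matrix=adj)
    logger.info("adjacency: %d channels, mean degree %.2f", n, graph.mean_degree)
    return graph


def _knn_adjacency(layout: ChannelLayout, k: int) -> AdjacencyGraph:
    n = len(layout)
    d = np.linalg.norm(layout.pos[:, None] - layout.pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in np.argsort(d[i])[:min(k, n - 1)]:
            adj[i, j] = adj[j, i] = True
    return AdjacencyGraph(names=layout.names, matrix=adj)


# ----------------------------------------------------------------------

@dataclass
class ClusterResult:
    clusters: list[dict]       # members, stat_sum, sign, p
    stat_map: np.ndarray       # channels x freqs (x times)
    stat: str
    n_perm: int
    seed: int | None
    settings: dict = field(default_factory=dict)

    @property
    def significant(self) -> list[dict]:
        alpha = self.settings.get("cluster_alpha", 0.05)
        return [c for c in self.clusters if c["p"] < alpha]

    def min_p(self) -> float:
        return min((c["p"] for c in self.clusters), default=1.0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stat": self.stat, "n_perm": self.n_perm, "seed": self.seed,
            "settings": self.settings,
            "clusters": [
                {"members": [list(map(int, m)) for m in c["members"]],
                 "stat_sum": float(c["stat_sum"]), "sign": int(c["sign"]),
                 "p": float(c["p"])}
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _dep_f_map(data: np.ndarray) -> np.ndarray:
    """Repeated-measures one-way F over conditions; data (P, C, ...)."""
    p, c = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    cond = data.mean(axis=0)
    part = data.mean(axis=1)
    ss_cond = p * ((cond - grand) ** 2).sum(axis=0)
    resid = data - cond[None] - part[:, None] + grand[None, None]
    ss_err = (resid ** 2).sum(axis=(0, 1))
    df1, df2 = c - 1, (c - 1) * (p - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    # degenerate points: error variance at floating-point noise level.
    # F = 0 when there is no condition effect either, a large sentinel when
    # a perfect effect sits on zero error variance.
    ss_tot = ((data - grand[None, None]) ** 2).sum(axis=(0, 1))
    degen = ss_err <= 1e-12 * np.maximum(ss_tot, 1e-300)
    if np.any(degen):
        logger.info("%d degenerate zero-variance points", int(degen.sum()))
        f = np.where(degen, np.where(ss_cond > 1e-12 * ss_tot, 1e12, 0.0), f)
    f = np.where(np.isfinite(f), f, 0.0)
    return f


def _dep_t_map(data: np.ndarray) -> np.ndarray:
    """One-sample t of participant effects against zero; data (P, ...)."""
    p = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(p))
    bad = ~np.isfinite(t)
    if np.any(bad):
        nz = bad & (np.abs(mean) > 0)
        if np.any(nz):  # zero variance, non-zero mean: infinitely significant
            t = np.where(nz, np.sign(mean) * 1e12, t)
        t = np.where(~np.isfinite(t), 0.0, t)
    return t


def _find_clusters(mask: np.ndarray, stat: np.ndarray,
                   adjacency: np.ndarray | None,
                   min_channels: int) -> list[tuple[list[tuple], float]]:
    """Union-find clustering of supra-threshold points.

    ``mask``/``stat`` are channels x freqs (x times). Neighbour relation:
    adjacent channels at the same grid point, or the same channel at an
    immediately adjacent frequency/time step.
    """
    if mask.ndim == 2:
        mask = mask[:, :, None]
        stat = stat[:, :, None]
        squeeze = True
    else:
        squeeze = False
    nch, nf, nt = mask.shape
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return []
    id_of = -np.ones(mask.size, dtype=np.int64)
    id_of[idx] = np.arange(idx.size)

    parent = np.arange(idx.size)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    coords = np.column_stack(np.unravel_index(idx, mask.shape))
    for pid, (ch, fi, ti) in enumerate(coords):
        flat_base = (fi * nt + ti)
        if fi + 1 < nf and mask[ch, fi + 1, ti]:
            union(pid, id_of[ch * nf * nt + (fi + 1) * nt + ti])
        if ti + 1 < nt and mask[ch, fi, ti + 1]:
            union(pid, id_of[ch * nf * nt + fi * nt + ti + 1])
        if adjacency is not None:
            for ch2 in np.flatnonzero(adjacency[ch]):
                if ch2 > ch and mask[ch2, fi, ti]:
                    union(pid, id_of[ch2 * nf * nt + flat_base])

    roots = np.array([find(i) for i in range(idx.size)])
    clusters = []
    for root in np.unique(roots):
        members_idx = coords[roots == root]
        if not _passes_channel_rule(members_idx, adjacency, min_channels):
            continue
        s = float(stat[tuple(members_idx.T)].sum())
        members = [tuple(m[:2]) if squeeze else tuple(m) for m in members_idx]
        clusters.append((members, s))
    return clusters


def _passes_channel_rule(members_idx: np.ndarray, adjacency: np.ndarray | None,
                         min_channels: int) -> bool:
    """>= min_channels distinct neighbouring channels at an overlapping point."""
    if min_channels <= 1:
        return True
    if adjacency is None:
        return False
    from collections import defaultdict
    by_point = defaultdict(list)
    for ch, fi, ti in members_idx:
        by_point[(fi, ti)].append(ch)
    for chans in by_point.values():
        if len(chans) < min_channels:
            continue
        chans = np.asarray(chans)
        sub = adjacency[np.ix_(chans, chans)]
        # largest connected component within this point's channel set
        seen = np.zeros(len(chans), dtype=bool)
        for s in range(len(chans)):
            if seen[s]:
                continue
            stack, comp = [s], 0
            while stack:
                v = stack.pop()
                if seen[v]:
                    continue
                seen[v] = True
                comp += 1
                stack.extend(np.flatnonzero(sub[v]))
            if comp >= min_channels:
                return True
    return False


def cluster_permutation_test(data: np.ndarray, stat: str = "dependent_F",
                             adjacency: AdjacencyGraph | np.ndarray | None = None,
                             point_alpha: float = 0.05,
                             cluster_alpha: float | None = None,
                             n_perm: int = 2000,
                             min_channels: int = 2,
                             seed: int | None = None) -> ClusterResult:
    """Monte-Carlo cluster test.

    Parameters
    ----------
    data
        ``dependent_F``: participants x conditions x channels x freqs (x times).
        ``dependent_t``: participants x channels x freqs (x times) participant
        effects (e.g. regression coefficients), tested against zero with a
        sign-flip null; two-tailed with ``cluster_alpha = .025`` per tail.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse Monte-Carlo p", stacklevel=2)
    adj = adjacency.matrix if isinstance(adjacency, AdjacencyGraph) else adjacency
    rng = np.random.default_rng(seed)
    data = np.asarray(data, dtype=float)

    if stat == "dependent_F":
        if data.ndim < 4:
            raise ValueError("dependent_F expects participants x conditions x channels x ...")
        p, c = data.shape[:2]
        if p < 2 or c < 2:
            raise ValueError("need >= 2 participants and >= 2 conditions")
        crit = stats.f.isf(point_alpha, c - 1, (c - 1) * (p - 1))
        if cluster_alpha is None:
            cluster_alpha = 0.05

        def observed_clusters():
            fmap = _dep_f_map(data)
            return fmap, _find_clusters(fmap > crit, fmap, adj, min_channels)

        def null_stat():
            perm = np.empty_like(data)
            for i in range(p):
                perm[i] = data[i, rng.permutation(c)]
            fmap = _dep_f_map(perm)
            cl = _find_clusters(fmap > crit, fmap, adj, min_channels)
            return max((s for _, s in cl), default=0.0)

        stat_map, obs = observed_clusters()
        null = np.array([null_stat() for _ in range(n_perm)])
        clusters = [
            {"members": members, "stat_sum": s, "sign": 1,
             "p": float((1 + np.sum(null >= s)) / (1 + n_perm))}
            for members, s in obs
        ]

    elif stat == "dependent_t":
        if data.ndim < 3:
            raise ValueError("dependent_t expects participants x channels x ...")
        p = data.shape[0]
        if p < 2:
            raise ValueError("need >= 2 participants")
        crit = stats.t.isf(point_alpha / 2.0, p - 1)
        if cluster_alpha is None:
            cluster_alpha = 0.025

        def clusters_of(tmap):
            pos = _find_clusters(tmap > crit, tmap, adj, min_channels)
            neg = _find_clusters(tmap < -crit, tmap, adj, min_channels)
            return ([(m, s, 1) for m, s in pos]
                    + [(m, s, -1) for m, s in neg])

        stat_map = _dep_t_map(data)
        obs = clusters_of(stat_map)
        signs_all = rng.choice([-1.0, 1.0], size=(n_perm, p))
        null = np.empty(n_perm)
        for k in range(n_perm):
            tmap = _dep_t_map(data * signs_all[k][(slice(None),) + (None,) * (data.ndim - 1)])
            cl = clusters_of(tmap)
            null[k] = max((abs(s) for _, s, _ in cl), default=0.0)
        clusters = [
            {"members": members, "stat_sum": s, "sign": sign,
             "p": float((1 + np.sum(null >= abs(s))) / (1 + n_perm))}
            for members, s, sign in obs
        ]
    else:
        raise ValueError(f"unknown stat {stat!r}")

    clusters.sort(key=lambda c: abs(c["stat_sum"]), reverse=True)
    return ClusterResult(
        clusters=clusters, stat_map=stat_map, stat=stat, n_perm=n_perm,
        seed=seed, settings={"point_alpha": point_alpha,
                             "cluster_alpha": cluster_alpha,
                             "min_channels": min_channels},
    )
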