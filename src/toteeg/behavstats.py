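"""Behavioural preprocessing and block-level repeated-measures statistics.

Covers the behavioural side of a time-on-task analysis: per-participant RT
trimming at k standard deviations, psychometric summaries per block x
stimulus contrast cell, one- and two-way within-participant ANOVAs with
Mauchly's sphericity test and the Greenhouse-Geisser correction, and Tukey
HSD post-hoc comparisons based on the studentized range distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "rt_trim", "psychometric_summary", "rm_anova", "tukey_hsd"]

logger = logging.getLogger(__name__)


def rt_trim(rts, k: float = 3.0) -> np.ndarray:
    """Inclusion mask: trials strictly within k SDs of the participant mean.

    Computed once over all of a participant's raw RTs (session-wide). A
    zero-SD series (all identical RTs) retains every trial.
    """
    x = np.asarray(rts, dtype=float)
    if np.sum(np.isfinite(x)) < 2:
        raise ValueError("need at least 2 finite RTs")
    mean = np.nanmean(x)
    sd = np.nanstd(x)  # population SD
    if sd == 0:
        return np.isfinite(x)
    return np.abs(x - mean) < k * sd


def psychometric_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant block x contrast psychometric cells.

    Returns tidy rows (participant, block, contrast, p_correct, p_confident,
    mean_rt) over the complete design grid; empty cells are missing values
    with a log entry.
    """
    g = table.groupby(["participant", "block", "contrast"], sort=True)
    out = g.agg(p_correct=("accuracy", "mean"),
                p_confident=("confidence", "mean"),
                mean_rt=("rt", "mean"),
                n_trials=("rt", "size")).reset_index()
    full = pd.MultiIndex.from_product(
        [sorted(table["participant"].unique()), sorted(table["block"].unique()),
         sorted(table["contrast"].unique())],
        names=["participant", "block", "contrast"])
    out = out.set_index(["participant", "block", "contrast"]).reindex(full).reset_index()
    n_empty = int(out["n_trials"].isna().sum())
    if n_empty:
        logger.warning("%d empty design cells left as missing", n_empty)
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    return out


# ----------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass
class AnovaResult:
    table: pd.DataFrame   # per effect: ss, df1, df2, F, p, eps, p_gg, partial_eta_sq, mauchly_W, mauchly_p
    design: str

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert-style, normalised)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _sphericity(scores: np.ndarray) -> tuple[float, float, float]:
    """Greenhouse-Geisser epsilon and Mauchly's test from n x k scores.

    Returns (epsilon, W, p). A 2-level factor has epsilon = 1 and W = 1
    identically. With n - 1 < k - 1 the covariance is singular: W and its p
    are undefined (NaN) while the trace-based epsilon is still returned.
    """
    n, k = scores.shape
    if k == 2:
        return 1.0, 1.0, 1.0
    c = _orthonormal_contrasts(k)
    s = np.cov(scores, rowvar=False, ddof=1)
    m = c @ s @ c.T
    p_dim = k - 1
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    eps = float(tr ** 2 / (p_dim * tr2)) if tr2 > 0 else 1.0
    eps = min(max(eps, 1.0 / p_dim), 1.0)

    if n - 1 < p_dim:
        return eps, np.nan, np.nan
    det = np.linalg.det(m)
    denom = (tr / p_dim) ** p_dim
    if det <= 0 or denom <= 0:
        return eps, 0.0, 0.0
    w = float(det / denom)
    d = 1.0 - (2.0 * p_dim ** 2 + p_dim + 2.0) / (6.0 * p_dim * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    df = p_dim * (p_dim + 1) / 2.0 - 1.0
    p_val = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return eps, w, p_val


def _effect_row(name, ss_eff, ss_err, df1, df2, scores) -> dict:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    f = ms_eff / ms_err if ms_err > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2))
    eps, w, p_mauchly = _sphericity(scores)
    p_gg = float(stats.f.sf(f, eps * df1, eps * df2))
    return {"effect": name, "ss": ss_eff, "ss_error": ss_err,
            "df1": df1, "df2": df2, "ms_error": ms_err, "F": f, "p": p,
            "eps": eps, "p_gg": p_gg,
            "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
            "mauchly_W": w, "mauchly_p": p_mauchly}


def rm_anova(data: np.ndarray, factor_names: tuple[str, ...] = ("A",)) -> AnovaResult:
    """Within-participant ANOVA for one or two fully-crossed factors.

    ``data`` is participants x levelsA (one factor) or participants x
    levelsA x levelsB. Missing cells are not supported: participants with
    any non-finite value are dropped with a warning; at least 3 complete
    participants are required. Greenhouse-Geisser epsilon is estimated from
    the sample covariance of the within-participant (contrast) scores; both
    the uncorrected p and the corrected p_gg are always reported.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
        names = (factor_names[0], "_dummy")
    elif y.ndim == 3:
        if len(factor_names) < 2:
            factor_names = (factor_names[0], "B")
        names = factor_names[:2]
    else:
        raise ValueError("data must be participants x levels (x levels)")

    complete = np.all(np.isfinite(y.reshape(y.shape[0], -1)), axis=1)
    if not complete.all():
        logger.warning("dropping %d participants with missing cells",
                       int((~complete).sum()))
        y = y[complete]
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need >= 3 complete participants")

    grand = y.mean()
    m_i = y.mean(axis=(1, 2))          # participant means
    m_j = y.mean(axis=(0, 2))          # A marginal means
    m_k = y.mean(axis=(0, 1))          # B marginal means
    m_ij = y.mean(axis=2)
    m_ik = y.mean(axis=1)
    m_jk = y.mean(axis=0)

    rows = []
    # main effect A
    ss_a = n * b * np.sum((m_j - grand) ** 2)
    ss_as = b * np.sum((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2)
    rows.append(_effect_row(names[0], ss_a, ss_as, a - 1, (a - 1) * (n - 1), m_ij))

    if b > 1:
        ss_b = n * a * np.sum((m_k - grand) ** 2)
        ss_bs = a * np.sum((m_ik - m_i[:, None] - m_k[None, :] + grand) ** 2)
        rows.append(_effect_row(names[1], ss_b, ss_bs, b - 1, (b - 1) * (n - 1), m_ik))

        ss_ab = n * np.sum((m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2)
        resid = (y - m_ij[:, :, None] - m_ik[:, None, :] - m_jk[None]
                 + m_i[:, None, None] + m_j[None, :, None] + m_k[None, None, :]
                 - grand)
        ss_abs = np.sum(resid ** 2)
        # interaction contrast scores per participant
        ca, cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
        scores = np.einsum("pa,nab,qb->npq", ca, y, cb).reshape(n, -1)
        df1 = (a - 1) * (b - 1)
        df2 = df1 * (n - 1)
        ms_err = ss_abs / df2
        f = (ss_ab / df1) / ms_err if ms_err > 0 else np.inf
        eps, w, p_m = _sphericity_from_scores(scores)
        rows.append({"effect": f"{names[0]}*{names[1]}", "ss": ss_ab,
                     "ss_error": ss_abs, "df1": df1, "df2": df2,
                     "ms_error": ms_err,
                     "F": f, "p": float(stats.f.sf(f, df1, df2)),
                     "eps": eps, "p_gg": float(stats.f.sf(f, eps * df1, eps * df2)),
                     "partial_eta_sq": ss_ab / (ss_ab + ss_abs) if ss_ab + ss_abs > 0 else 0.0,
                     "mauchly_W": w, "mauchly_p": p_m})

    design = " x ".join(str(s) for s in ((a, b) if b > 1 else (a,)))
    return AnovaResult(table=pd.DataFrame(rows), design=f"within {design}, n={n}")


def _sphericity_from_scores(scores: np.ndarray) -> tuple[float, float, float]:
    """Sphericity quantities when the contrast scores are already formed."""
    n, p_dim = scores.shape
    if p_dim == 1:
        return 1.0, 1.0, 1.0
    m = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    eps = float(tr ** 2 / (p_dim * tr2)) if tr2 > 0 else 1.0
    eps = min(max(eps, 1.0 / p_dim), 1.0)
    if n - 1 < p_dim:
        return eps, np.nan, np.nan
    det = np.linalg.det(m)
    denom = (tr / p_dim) ** p_dim
    if det <= 0 or denom <= 0:
        return eps, 0.0, 0.0
    w = float(det / denom)
    d = 1.0 - (2.0 * p_dim ** 2 + p_dim + 2.0) / (6.0 * p_dim * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    df = p_dim * (p_dim + 1) / 2.0 - 1.0
    return eps, w, float(stats.chi2.sf(chi2, df))


def tukey_hsd(means, ms_error: float, df_error: float, n_per_cell: int) -> pd.DataFrame:
    """Tukey HSD over balanced cell means with a given error mean square.

    ``q = |m_i - m_j| / sqrt(MS_err / n)`` referred to the studentized range
    distribution with k groups and df_error degrees of freedom.
    """
    m = np.asarray(means, dtype=float)
    k = m.size
    if k < 2:
        raise ValueError("need at least 2 means")
    if ms_error < 0 or n_per_cell < 1:
        raise ValueError("invalid error term")
    se = np.sqrt(ms_error / n_per_cell)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = m[i] - m[j]
        if se == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append({"level_i": i, "level_j": j, "mean_diff": float(diff),
                     "q": float(q), "p_adj": min(max(p, 0.0), 1.0)})
    return pd.DataFrame(rows)
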