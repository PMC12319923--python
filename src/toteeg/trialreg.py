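"""Single-trial multiple regression with hierarchical two-stage inference.

Stage one fits, per participant, an ordinary-least-squares model of an EEG
measure on behaviour:

``EEG = a + b_conf*Confidence + b_diff*Difficulty + b_corr*Accuracy
        + b_RT*rank(RT) [+ b_ToT*rank(TrialOrder)] + error``

Confidence and accuracy are binary (0/1); difficulty is the numeric
stimulus-contrast value; continuous variables (RT, trial order, and by
default the EEG outcome itself) are rank-transformed to blunt outlying
trials. Stage two tests the participant coefficients against zero (one-sample
t with Cohen's d and Benjamini-Hochberg FDR for scalar families; cluster
permutation via :mod:`toteeg.permstats` for time-frequency maps). Nested
models with and without trial order are compared per participant by AIC
(Gaussian form, ``n*ln(RSS/n) + 2k`` with the error variance counted in k)
and the per-participant ``dAIC = AIC(noToT) - AIC(withToT)`` by a two-tailed
paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .permstats import AdjacencyGraph, ClusterResult, cluster_permutation_test

__all__ = [
    "RegressionFit", "ModelComparison",
    "rank_transform", "fit_trial_regression", "fit_trial_regression_maps",
    "group_level_test", "group_level_cluster_test",
    "compare_models_aic", "coefficient_contrast",
]

logger = logging.getLogger(__name__)

#: smallest representable p, reported for degenerate zero-variance group tests
TINY_P = float(np.finfo(float).tiny)

PREDICTORS_NO_TOT = ("confidence", "difficulty", "accuracy", "rt")
PREDICTORS_WITH_TOT = PREDICTORS_NO_TOT + ("tot",)


def rank_transform(values) -> np.ndarray:
    """Average-tie ranks 1..n; missing values stay missing."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("rank_transform needs at least one finite value")
    out[finite] = stats.rankdata(x[finite], method="average")
    return out


@dataclass
class RegressionFit:
    participant: int
    outcome: str
    model: str                     # "noToT" | "withToT"
    intercept: float
    coefs: dict[str, float]        # predictor -> coefficient (NaN if undefined)
    resid_var: float
    n: int
    aic: float
    r_squared: float
    trial_index: np.ndarray = field(repr=False, default=None)


def _design_matrix(table: pd.DataFrame, include_tot: bool) -> tuple[np.ndarray, list[str]]:
    cols = {
        "confidence": table["confidence"].to_numpy(float),
        "difficulty": table["contrast"].to_numpy(float),
        "accuracy": table["accuracy"].to_numpy(float),
        "rt": rank_transform(table["rt"].to_numpy(float)),
    }
    if include_tot:
        cols["tot"] = rank_transform(table["trial_order"].to_numpy(float))
    names = list(cols)
    X = np.column_stack([np.ones(len(table))] + [cols[c] for c in names])
    return X, names


def fit_trial_regression(outcome, table: pd.DataFrame, include_tot: bool = False,
                         outcome_name: str = "eeg",
                         rank_outcome: bool = True) -> RegressionFit:
    """OLS of one EEG measure on behaviour (optionally + trial order).

    Rows where the outcome is missing (e.g. no detected alpha peak) are
    dropped; ``trial_index`` records which rows entered, so a model pair can
    be fitted on identical trial sets. Rank-deficient designs (a constant
    predictor) leave that coefficient undefined (NaN) with a log entry.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(table):
        raise ValueError("outcome must align with the trial table rows")
    keep = np.isfinite(y)
    table = table.loc[keep]
    y = y[keep]
    if rank_outcome:
        y = rank_transform(y)

    X, names = _design_matrix(table, include_tot)
    n, k_cols = X.shape
    if n <= k_cols:
        raise ValueError("too few trials for the number of predictors")

    constant = [names[j - 1] for j in range(1, k_cols)
                if np.ptp(X[:, j]) == 0]
    usable = [j for j in range(k_cols)
              if j == 0 or names[j - 1] not in constant]
    if constant:
        logger.warning("participant %s: constant predictor(s) %s left undefined",
                       table["participant"].iloc[0], constant)
    beta_u, _, rank, _ = np.linalg.lstsq(X[:, usable], y, rcond=None)
    fitted = X[:, usable] @ beta_u
    rss = float(np.sum((y - fitted) ** 2))

    coefs = {name: np.nan for name in names}
    for pos, j in enumerate(usable):
        if j == 0:
            intercept = float(beta_u[pos])
        else:
            coefs[names[j - 1]] = float(beta_u[pos])

    k = len(usable) + 1  # slopes + intercept + error variance
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return RegressionFit(
        participant=int(table["participant"].iloc[0]), outcome=outcome_name,
        model="withToT" if include_tot else "noToT",
        intercept=intercept, coefs=coefs,
        resid_var=rss / max(n - len(usable), 1), n=n, aic=float(aic),
        r_squared=r2, trial_index=np.flatnonzero(keep),
    )


def fit_trial_regression_maps(outcomes: np.ndarray, table: pd.DataFrame,
                              include_tot: bool = False,
                              rank_outcome: bool = True):
    """Vectorised OLS for many outcomes sharing one design.

    ``outcomes`` is trials x points (e.g. flattened channel x freq x time
    power). Returns ``(coefs, aic)`` with coefs of shape
    (n_predictors, points) ordered as the model's predictor list. Points with
    any missing trial value are fitted on their own complete rows only when
    the missing pattern is shared; fully missing points return NaN.
    """
    Y = np.asarray(outcomes, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(table):
        raise ValueError("outcomes must be trials x points, aligned to table")
    X, names = _design_matrix(table, include_tot)
    n, k_cols = X.shape

    if rank_outcome:
        Yr = np.full_like(Y, np.nan)
        finite = np.isfinite(Y)
        # column-wise ranks (loop is fine: points >> trials cost dominated by lstsq)
        for j in range(Y.shape[1]):
            fj = finite[:, j]
            if fj.any():
                Yr[fj, j] = stats.rankdata(Y[fj, j], method="average")
        Y = Yr

    complete = np.all(np.isfinite(Y), axis=0)
    coefs = np.full((len(names), Y.shape[1]), np.nan)
    aic = np.full(Y.shape[1], np.nan)
    if complete.any():
        Yc = Y[:, complete]
        beta, _, _, _ = np.linalg.lstsq(X, Yc, rcond=None)
        rss = np.sum((Yc - X @ beta) ** 2, axis=0)
        k = k_cols + 1
        aic[complete] = n * np.log(np.maximum(rss, 1e-300) / n) + 2 * k
        coefs[:, complete] = beta[1:]
    # points with partial missingness: fit individually
    partial = ~complete & np.any(np.isfinite(Y), axis=0)
    for j in np.flatnonzero(partial):
        fj = np.isfinite(Y[:, j])
        if fj.sum() <= k_cols + 1:
            continue
        beta, _, _, _ = np.linalg.lstsq(X[fj], Y[fj, j], rcond=None)
        rss = float(np.sum((Y[fj, j] - X[fj] @ beta) ** 2))
        aic[j] = fj.sum() * np.log(max(rss, 1e-300) / fj.sum()) + 2 * (k_cols + 1)
        coefs[:, j] = beta[1:]
    return coefs, aic


# ----------------------------------------------------------------------
# group level

def _one_sample_t(values: np.ndarray) -> tuple[float, float, float]:
    """t, p (two-tailed), Cohen's d; degenerate zero variance handled."""
    values = values[np.isfinite(values)]
    n = len(values)
    mean = values.mean()
    sd = values.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, 0.0
        # all coefficients identical and non-zero: maximally significant
        return np.sign(mean) * np.inf, TINY_P, np.sign(mean) * np.inf
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), float(mean / sd)


def group_level_test(fits: list[RegressionFit],
                     predictors: tuple[str, ...] | None = None,
                     fdr_alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t per predictor across participants, with BH-FDR.

    Participants whose coefficient is undefined (rank-deficient design) are
    excluded from that predictor's test. Requires >= 3 participants.
    """
    if len({f.participant for f in fits}) < 3:
        raise ValueError("group-level test needs >= 3 participants")
    if predictors is None:
        predictors = tuple(fits[0].coefs.keys())
    rows = []
    for pred in predictors:
        vals = np.array([f.coefs.get(pred, np.nan) for f in fits])
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            raise ValueError(f"fewer than 3 defined coefficients for {pred!r}")
        t, p, d = _one_sample_t(vals)
        rows.append({"predictor": pred, "mean_coef": float(vals.mean()),
                     "t": t, "df": len(vals) - 1, "p": p, "cohen_d": d,
                     "n": len(vals)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = stats.false_discovery_control(
        np.clip(out["p"].to_numpy(), TINY_P, 1.0), method="bh")
    out["significant"] = out["p_fdr"] < fdr_alpha
    return out


def group_level_cluster_test(coef_maps: np.ndarray,
                             adjacency: AdjacencyGraph | None,
                             n_perm: int = 2000,
                             cluster_alpha: float = 0.025,
                             min_channels: int = 2,
                             seed: int | None = None) -> ClusterResult:
    """Cluster permutation of coefficient maps (participants x ch x f (x t))."""
    return cluster_permutation_test(
        coef_maps, stat="dependent_t", adjacency=adjacency,
        cluster_alpha=cluster_alpha, n_perm=n_perm,
        min_channels=min_channels, seed=seed)


@dataclass
class ModelComparison:
    participants: list[int]
    delta_aic: np.ndarray   # AIC(noToT) - AIC(withToT), positive favours ToT
    t: float
    p: float

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.delta_aic))


def compare_models_aic(fits_no: list[RegressionFit],
                       fits_with: list[RegressionFit]) -> ModelComparison:
    """Per-participant dAIC and two-tailed paired t against zero.

    Both fits of a pair must come from identical trial sets, otherwise the
    AICs are not commensurable.
    """
    by_pid_no = {f.participant: f for f in fits_no}
    by_pid_with = {f.participant: f for f in fits_with}
    if set(by_pid_no) != set(by_pid_with):
        raise ValueError("mismatched participants between models")
    pids = sorted(by_pid_no)
    for pid in pids:
        a, b = by_pid_no[pid], by_pid_with[pid]
        if a.n != b.n or not np.array_equal(a.trial_index, b.trial_index):
            raise ValueError(f"participant {pid}: models fitted on different trial sets")
    delta = np.array([by_pid_no[p].aic - by_pid_with[p].aic for p in pids])
    t, p, _ = _one_sample_t(delta)
    return ModelComparison(participants=pids, delta_aic=delta, t=t, p=p)


def coefficient_contrast(fits_no: list[RegressionFit],
                         fits_with: list[RegressionFit],
                         predictor: str = "rt") -> dict:
    """Paired test of one coefficient between the two models.

    Differences are ``withToT - noToT`` per participant, tested against zero
    (two-tailed)."""
    by_pid_no = {f.participant: f for f in fits_no}
    by_pid_with = {f.participant: f for f in fits_with}
    if set(by_pid_no) != set(by_pid_with):
        raise ValueError("mismatched participants between models")
    pids = sorted(by_pid_no)
    diffs = np.array([
        by_pid_with[p].coefs[predictor] - by_pid_no[p].coefs[predictor]
        for p in pids
    ])
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) < 3:
        raise ValueError("fewer than 3 defined coefficient pairs")
    t, p, d = _one_sample_t(diffs)
    return {"predictor": predictor, "mean_diff": float(diffs.mean()),
            "t": t, "p": p, "cohen_d": d, "n": len(diffs)}
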