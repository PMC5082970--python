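"""Inter-network connectivity: constrained maximal lagged correlation.

For every pair of network time courses the Pearson correlation is evaluated
at every integer lag in [-L, L] (default L = 12 TRs), where the lagged
series is *circularly* shifted so all T samples are always used.  The lag
minimizing the correlation p value (equivalently, for fixed T, maximizing
|r|) is the pair's optimal lag; its correlation is Fisher z-transformed
(z = atanh r) and carried into group ANCOVA (education and total
grey-matter volume as nuisance, Bonferroni over pairs), pairwise group
contrasts, and brain-behaviour partial correlations.

Because the maximum is taken over 25 lags, the naive p value (t transform
with df = T-2) overstates significance; a circular-rotation permutation p
is therefore computed alongside it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "LagCorrResult",
    "detrend_timecourse",
    "circular_lagged_r",
    "max_lagged_correlation",
    "fisher_z",
    "subject_pair_table",
    "group_pair_table",
    "group_anova_z",
    "pairwise_contrasts",
    "behavior_partial_correlation",
    "ledd_fc_check",
    "rotation_null_p",
]

DEFAULT_MAX_LAG = 12


@dataclass(frozen=True)
class LagCorrResult:
    """Optimal-lag correlation for one subject and one network pair."""

    pair: tuple[str, str]
    subject_id: str
    optimal_lag: int
    r: float
    p: float
    z: float


def detrend_timecourse(tc: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (and mean) from a series."""
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1 or tc.size < 3:
        raise ValueError("timecourse must be 1D with T >= 3")
    if np.ptp(tc) == 0:
        warnings.warn("constant time course; returning zeros", stacklevel=2)
        return np.zeros_like(tc)
    t = np.arange(tc.size, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, tc, rcond=None)
    return tc - X @ beta


def circular_lagged_r(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Pearson correlation of x_t with y_(t+lag), y circularly shifted.

    All T samples are used at every lag (no truncation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1D series with T >= 3")
    for name, s in (("x", x), ("y", y)):
        if np.ptp(s) == 0:
            raise ValueError(f"series {name} is constant; correlation undefined")
    # y_(t+lag) sits at index t after rolling y left by `lag`
    return float(np.corrcoef(x, np.roll(y, -lag))[0, 1])


def _p_from_r(r: float, T: int) -> float:
    """Two-sided p for a Pearson r via the t transform with df = T - 2."""
    df = T - 2
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def max_lagged_correlation(
    x: np.ndarray, y: np.ndarray, max_lag: int = DEFAULT_MAX_LAG
) -> tuple[int, float, float]:
    """Constrained maximal lagged correlation over lags in [-max_lag, max_lag].

    Evaluates the circular lagged Pearson correlation at all 2*max_lag + 1
    integer lags and returns ``(optimal_lag, r, p)`` for the lag with the
    best (smallest) p value — for fixed T, the lag maximizing |r|.  Ties are
    broken by smaller |lag|, then by the negative lag.
    """
    x = np.asarray(x, dtype=float)
    T = x.size
    if T <= 2 * max_lag:
        raise ValueError(f"T={T} must exceed 2*max_lag={2 * max_lag}")
    # lag order implementing the tie-break: 0, -1, 1, -2, 2, ...
    best_lag, best_r = None, None
    for k in range(0, max_lag + 1):
        for lag in ((-k, k) if k else (0,)):
            r = circular_lagged_r(x, y, lag)
            if best_r is None or abs(r) > abs(best_r):
                best_lag, best_r = lag, r
    return best_lag, best_r, _p_from_r(best_r, T)


def fisher_z(r: float) -> float:
    """Fisher z-transform, z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z-transform")
    return np.arctanh(r) if r.ndim else float(np.arctanh(r))


def rotation_null_p(
    x: np.ndarray,
    y: np.ndarray,
    observed_abs_r: float,
    max_lag: int = DEFAULT_MAX_LAG,
    n_rotations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for the maximal lagged |r| under a circular-rotation null.

    Rotating one series by a random offset preserves both autocorrelation
    structures while destroying the cross-coupling, giving a null for the
    max-over-lags statistic that the naive df = T-2 p value ignores.
    """
    rng = np.random.default_rng(seed)
    T = len(x)
    count = 0
    offsets = rng.integers(max_lag + 1, T - max_lag, size=n_rotations)
    for off in offsets:
        y_rot = np.roll(y, int(off))
        _, r, _ = max_lagged_correlation(x, y_rot, max_lag)
        if abs(r) >= observed_abs_r:
            count += 1
    return (1 + count) / (n_rotations + 1)


# ---------------------------------------------------------------------------
# Tables over subjects and groups


def network_pairs(names: tuple[str, ...] | list[str]) -> list[tuple[str, str]]:
    """All unordered network pairs, in combination order."""
    return list(itertools.combinations(names, 2))


def subject_pair_table(
    timecourses: dict[str, pd.DataFrame | np.ndarray],
    network_names: list[str] | tuple[str, ...],
    max_lag: int = DEFAULT_MAX_LAG,
    detrend: bool = True,
) -> pd.DataFrame:
    """Per-subject optimal-lag correlations for every network pair.

    ``timecourses`` maps subject_id to a (T, n_networks) array or DataFrame
    whose columns follow ``network_names``.  Returns a long-format frame
    with columns subject_id, pair, network_a, network_b, lag, r, p, z.
    """
    rows = []
    for sid, tc in timecourses.items():
        arr = np.asarray(tc, dtype=float)
        if arr.shape[1] != len(network_names):
            raise ValueError(
                f"subject {sid}: {arr.shape[1]} columns != {len(network_names)} networks"
            )
        cols = {n: arr[:, i] for i, n in enumerate(network_names)}
        if detrend:
            cols = {n: detrend_timecourse(v) for n, v in cols.items()}
        for a, b in network_pairs(network_names):
            lag, r, p = max_lagged_correlation(cols[a], cols[b], max_lag)
            rows.append(
                {
                    "subject_id": sid, "pair": f"{a}_{b}", "network_a": a,
                    "network_b": b, "lag": lag, "r": r, "p": p,
                    "z": fisher_z(r),
                }
            )
    return pd.DataFrame(rows)


def group_pair_table(
    pair_table: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Group means of lag, r and p per network pair (study-table layout).

    Mean lags are means of integer per-subject optimal lags, reported to
    3 decimals.
    """
    merged = pair_table.merge(
        participants[["participant_id", "group"]],
        left_on="subject_id", right_on="participant_id",
    )
    out = (
        merged.groupby(["pair", "group"], sort=False)
        .agg(
            mean_lag=("lag", "mean"), mean_r=("r", "mean"),
            mean_p=("p", "mean"), mean_z=("z", "mean"), n=("z", "size"),
        )
        .reset_index()
    )
    out["mean_lag"] = out["mean_lag"].round(3)
    return out


def _ancova_fit(
    z: np.ndarray, groups: np.ndarray, nuisance: np.ndarray | None
):
    """OLS of z on group cell means plus centred nuisance columns."""
    z = np.asarray(z, dtype=float)
    labels = pd.Categorical(groups)
    G = pd.get_dummies(labels).to_numpy(dtype=float)  # cell-means coding
    cols = [G]
    if nuisance is not None and nuisance.size:
        N = np.asarray(nuisance, dtype=float)
        if N.ndim == 1:
            N = N[:, None]
        N = N - N.mean(axis=0)
        cols.append(N)
    X = np.column_stack(cols)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(
            f"design nearly collinear (condition number {cond:.2e})", stacklevel=3
        )
    model = sm.OLS(z, X).fit()
    return model, list(labels.categories), G.shape[1]


def group_anova_z(
    z: np.ndarray,
    groups: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> tuple[float, tuple[int, int], float]:
    """ANCOVA F test for the group factor on Fisher-z values.

    Returns (F, (df1, df2), p) for the hypothesis that all group means are
    equal after adjusting for the nuisance covariates.
    """
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    model, cats, n_groups = _ancova_fit(z, groups, nuisance)
    # all pairwise-adjacent equalities of the group cell means
    R = np.zeros((n_groups - 1, model.params.size))
    for i in range(n_groups - 1):
        R[i, i], R[i, i + 1] = 1.0, -1.0
    ftest = model.f_test(R)
    return float(ftest.fvalue), (int(ftest.df_num), int(ftest.df_denom)), float(ftest.pvalue)


def pairwise_contrasts(
    z: np.ndarray,
    groups: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> dict[tuple[str, str], tuple[float, int, float]]:
    """Covariate-adjusted t for each group difference, shared error variance.

    Returns {(g2, g1): (t, df, p)} for the contrast mean(g2) - mean(g1),
    for every unordered group pair, from the single full-model fit.
    """
    model, cats, n_groups = _ancova_fit(np.asarray(z, float), np.asarray(groups), nuisance)
    out: dict[tuple[str, str], tuple[float, int, float]] = {}
    for i, j in itertools.combinations(range(n_groups), 2):
        c = np.zeros(model.params.size)
        c[j], c[i] = 1.0, -1.0
        tt = model.t_test(c)
        out[(str(cats[j]), str(cats[i]))] = (
            float(np.squeeze(tt.tvalue)), int(tt.df_denom), float(np.squeeze(tt.pvalue)),
        )
    return out


def inter_network_anova_table(
    pair_table: pd.DataFrame,
    participants: pd.DataFrame,
    nuisance_cols: tuple[str, ...] = ("education", "gm_volume"),
) -> pd.DataFrame:
    """Group ANCOVA per pair with Bonferroni over all pairs tested.

    The Bonferroni factor is the number of pairs actually present in
    ``pair_table`` (10 for five networks).
    """
    merged = pair_table.merge(
        participants, left_on="subject_id", right_on="participant_id"
    )
    pairs = list(dict.fromkeys(pair_table["pair"]))
    n_pairs = len(pairs)
    rows = []
    for pair in pairs:
        sub = merged[merged["pair"] == pair]
        nuis = sub[list(nuisance_cols)].to_numpy(float) if nuisance_cols else None
        F, (df1, df2), p = group_anova_z(
            sub["z"].to_numpy(), sub["group"].to_numpy(), nuis
        )
        contrasts = pairwise_contrasts(
            sub["z"].to_numpy(), sub["group"].to_numpy(), nuis
        )
        row = {
            "pair": pair, "F": F, "df1": df1, "df2": df2, "p": p,
            "p_bonferroni": min(1.0, p * n_pairs),
        }
        for (g2, g1), (t, df, pt) in contrasts.items():
            row[f"t_{g2}_vs_{g1}"] = t
            row[f"p_{g2}_vs_{g1}"] = pt
        rows.append(row)
    return pd.DataFrame(rows)


def behavior_partial_correlation(
    z: np.ndarray,
    score: np.ndarray,
    nuisance: np.ndarray,
) -> tuple[float, float, int]:
    """Partial Pearson correlation of z with a cognitive score, nuisance removed.

    Both variables are residualized on [1, nuisance]; p is two-sided with
    df = n - 2 - k for k nuisance columns (n - 3 for the single
    grey-matter-volume covariate).  Incomplete cases are dropped.
    """
    z = np.asarray(z, dtype=float)
    score = np.asarray(score, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    ok = np.isfinite(z) & np.isfinite(score) & np.all(np.isfinite(nuisance), axis=1)
    if ok.sum() < ok.size:
        warnings.warn(f"dropping {int(ok.size - ok.sum())} incomplete cases", stacklevel=2)
    z, score, nuisance = z[ok], score[ok], nuisance[ok]
    n, k = z.size, nuisance.shape[1]
    if n < 5:
        raise ValueError(f"need >= 5 complete cases, have {n}")
    X = np.column_stack([np.ones(n), nuisance])
    rz = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
    rs = score - X @ np.linalg.lstsq(X, score, rcond=None)[0]
    if rz.std() == 0 or rs.std() == 0:
        raise ValueError("zero-variance residuals; partial correlation undefined")
    r = float(np.corrcoef(rz, rs)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def ledd_fc_check(
    fc_values: dict[str, np.ndarray],
    ledd: np.ndarray,
) -> pd.DataFrame:
    """Sensitivity check: dopaminergic dose (LEDD) vs per-network FC summaries.

    Plain Pearson correlations, reported uncorrected; intended for the
    treated (HOM) group only.
    """
    ledd = np.asarray(ledd, dtype=float)
    if np.ptp(ledd[np.isfinite(ledd)]) == 0:
        raise ValueError("LEDD is constant; correlation undefined")
    rows = []
    for name, vals in fc_values.items():
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals) & np.isfinite(ledd)
        if ok.sum() < 4:
            warnings.warn(f"network {name}: n={int(ok.sum())} < 4, skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(ledd[ok], vals[ok])
        rows.append({"network": name, "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)
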