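"""Longitudinal inference for repeated measures on a small cohort.

The central tool is a linear mixed model for one within-participant time
factor with a *compound-symmetry* covariance structure: every pair of
observations from the same participant shares one common covariance
``sigma^2 * rho`` and one variance ``sigma^2``.  Estimation is by
restricted maximum likelihood (REML) with the correlation profiled on a
closed-form scale parameter, which keeps the fit exact and fast for the
cohort sizes this package targets (tens of participants, a handful of
levels).  Participants with missing levels contribute their observed
cells through the likelihood — no imputation.

Also provided: ordered pairwise period contrasts, a tie-corrected Friedman
test with exact permutation enumeration for small block counts, and a
Spearman rank correlation wrapper.  All tests are two-sided; the
conventional significance level is .05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class ConvergenceError(RuntimeError):
    """The covariance optimization failed to produce a usable fit."""


def _pair_order(k: int) -> list[tuple[int, int]]:
    """Pairwise contrast order: adjacent pairs first, then wider spans.

    For three periods this is (second - third), (third - postpartum),
    (second - postpartum) — the order period comparisons are reported in.
    """
    return sorted(itertools.combinations(range(k), 2),
                  key=lambda ij: (ij[1] - ij[0], ij[0]))


@dataclass
class ModelResult:
    """Fitted compound-symmetry model: means, contrasts, variance components."""

    levels: list
    means: pd.DataFrame              # level, estimate, se, ci_low, ci_high
    contrasts: pd.DataFrame          # level_a, level_b, estimate, se, ci_low, ci_high, p
    overall_p: float
    sigma2: float                    # total variance
    rho: float                       # within-participant correlation
    df_resid: float
    n_participants: int
    n_obs: int
    converged: bool = True
    dropped_levels: list = field(default_factory=list)

    @property
    def between_variance(self) -> float:
        return self.sigma2 * self.rho

    @property
    def residual_variance(self) -> float:
        return self.sigma2 * (1.0 - self.rho)


def _cs_r_inv_quad(R_rows: np.ndarray, rho: float):
    """Closed-form pieces of R^{-1} for an m x m compound-symmetry block."""
    m = R_rows
    a = 1.0 / (1.0 - rho)
    b = -rho / ((1.0 - rho) * (1.0 - rho + rho * m))
    logdet = (m - 1) * np.log(1.0 - rho) + np.log(1.0 - rho + rho * m)
    return a, b, logdet


def fit_cs_model(table: pd.DataFrame, levels: list | None = None,
                 alpha: float = 0.05) -> ModelResult:
    """REML fit of a cell-means model with compound-symmetry covariance.

    ``table`` holds one row per observed participant x level cell with
    columns ``participant_id``, ``level``, ``value`` (at most one row per
    cell).  ``levels`` declares the ordered level set; levels with zero
    observations are dropped with a warning.  Returns marginal level means
    with 95% CIs, all ordered pairwise contrasts with model-based standard
    errors and two-sided p-values (no multiplicity adjustment), and an
    overall Wald F test of the time effect.

    Degrees of freedom use the between-within convention
    ``N - n_participants - (k - 1)``, which reduces to ``(n-1)(k-1)`` for
    balanced complete data and makes the two-level complete-pair contrast
    identical to the paired t test.
    """
    df = table.dropna(subset=["value"]).copy()
    if levels is None:
        levels = list(pd.unique(df["level"]))
    observed = set(df["level"])
    dropped = [lv for lv in levels if lv not in observed]
    for lv in dropped:
        warnings.warn(f"level {lv!r} has zero observations and was dropped",
                      stacklevel=2)
    levels = [lv for lv in levels if lv in observed]
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 observed levels")
    if df.duplicated(["participant_id", "level"]).any():
        raise ValueError("at most one observation per participant x level")
    df = df[df["level"].isin(levels)]
    pids = list(pd.unique(df["participant_id"]))
    n_subj = len(pids)
    if n_subj < 2:
        raise ValueError("need at least 2 participants")
    N = len(df)

    lv_index = {lv: j for j, lv in enumerate(levels)}
    groups = []
    for pid in pids:
        g = df[df["participant_id"] == pid]
        y = g["value"].to_numpy(dtype=float)
        X = np.zeros((len(g), k))
        X[np.arange(len(g)), [lv_index[lv] for lv in g["level"]]] = 1.0
        groups.append((y, X))

    m_max = max(len(y) for y, _ in groups)
    rho_lo = -1.0 / (m_max - 1) + 1e-9 if m_max > 1 else -1.0 + 1e-9

    def profile(rho: float):
        XtViX = np.zeros((k, k))
        XtViy = np.zeros(k)
        logdet = 0.0
        for y, X in groups:
            m = len(y)
            a, b, ld = _cs_r_inv_quad(m, rho)
            # R^{-1} v = a v + b * sum(v) * 1
            Xs, ys = X.sum(axis=0), y.sum()
            XtViX += a * X.T @ X + b * np.outer(Xs, Xs)
            XtViy += a * X.T @ y + b * ys * Xs
            logdet += ld
        beta = np.linalg.solve(XtViX, XtViy)
        rss = 0.0
        for y, X in groups:
            r = y - X @ beta
            a, b, _ = _cs_r_inv_quad(len(y), rho)
            rss += a * r @ r + b * r.sum() ** 2
        return beta, XtViX, logdet, rss

    def neg2_reml(rho: float) -> float:
        try:
            beta, XtViX, logdet, rss = profile(rho)
        except np.linalg.LinAlgError:
            return np.inf
        if rss <= 0:
            return -np.inf
        sigma2 = rss / (N - k)
        sign, ld_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return (N - k) * np.log(sigma2) + logdet + ld_x

    # degenerate zero-variance data: exact means, zero-width intervals
    beta0, XtViX0, _, rss0 = profile(0.0)
    if rss0 <= 1e-12 * max(1.0, float(np.abs(beta0).max()) ** 2):
        return _degenerate_result(levels, beta0, n_subj, N, k, dropped)

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(rho_lo, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-12})
    rho = float(res.x)
    beta, XtViX, _, rss = profile(rho)
    sigma2 = rss / (N - k)
    if not np.isfinite(sigma2) or sigma2 < 0:
        raise ConvergenceError(
            f"covariance optimization failed (rho={rho}, rss={rss})")
    cov_beta = sigma2 * np.linalg.inv(XtViX)

    df_resid = max(float(N - n_subj - (k - 1)), 1.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df_resid)

    se = np.sqrt(np.diag(cov_beta))
    means = pd.DataFrame({
        "level": levels, "estimate": beta, "se": se,
        "ci_low": beta - tcrit * se, "ci_high": beta + tcrit * se,
    })

    rows = []
    for i, j in _pair_order(k):
        c = np.zeros(k)
        c[i], c[j] = 1.0, -1.0
        est = float(c @ beta)
        cse = float(np.sqrt(c @ cov_beta @ c))
        tval = est / cse if cse > 0 else np.inf * np.sign(est)
        p = 2 * stats.t.sf(abs(tval), df_resid) if cse > 0 else (
            1.0 if est == 0 else 0.0)
        rows.append({
            "level_a": levels[i], "level_b": levels[j], "estimate": est,
            "se": cse, "ci_low": est - tcrit * cse,
            "ci_high": est + tcrit * cse, "p": p,
        })
    contrasts = pd.DataFrame(rows)

    C = np.zeros((k - 1, k))
    for r in range(k - 1):
        C[r, r], C[r, r + 1] = 1.0, -1.0
    cb = C @ beta
    F = float(cb @ np.linalg.solve(C @ cov_beta @ C.T, cb)) / (k - 1)
    overall_p = float(stats.f.sf(F, k - 1, df_resid))

    return ModelResult(levels=levels, means=means, contrasts=contrasts,
                       overall_p=overall_p, sigma2=float(sigma2),
                       rho=rho, df_resid=df_resid, n_participants=n_subj,
                       n_obs=N, converged=True, dropped_levels=dropped)


def _degenerate_result(levels, beta, n_subj, N, k, dropped) -> ModelResult:
    means = pd.DataFrame({
        "level": levels, "estimate": beta, "se": 0.0,
        "ci_low": beta, "ci_high": beta,
    })
    rows = []
    for i, j in _pair_order(k):
        est = float(beta[i] - beta[j])
        rows.append({"level_a": levels[i], "level_b": levels[j],
                     "estimate": est, "se": 0.0, "ci_low": est,
                     "ci_high": est, "p": 1.0 if est == 0 else 0.0})
    any_diff = any(r["estimate"] != 0 for r in rows)
    return ModelResult(
        levels=levels, means=means, contrasts=pd.DataFrame(rows),
        overall_p=0.0 if any_diff else 1.0, sigma2=0.0, rho=0.0,
        df_resid=max(float(N - n_subj - (k - 1)), 1.0),
        n_participants=n_subj, n_obs=N, converged=True,
        dropped_levels=dropped)


def period_contrast(period_means: dict | pd.Series,
                    order: list | None = None) -> pd.DataFrame:
    """Ordered pairwise differences of supplied period means.

    For the default three-period layout this yields (second - third,
    third - postpartum, second - postpartum); differences are taken
    earlier-minus-later, so a positive value is a decline over time.
    """
    if order is None:
        order = list(period_means.keys()) if isinstance(period_means, dict) \
            else list(period_means.index)
    vals = {k: float(period_means[k]) for k in order}
    rows = [{"level_a": order[i], "level_b": order[j],
             "difference": vals[order[i]] - vals[order[j]]}
            for i, j in _pair_order(len(order))]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Friedman test


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a blocks x levels rank matrix."""
    b, k = ranks.shape
    col = ranks.sum(axis=0)
    A = float((ranks ** 2).sum())
    C = b * k * (k + 1) ** 2 / 4.0
    num = (k - 1) * float(((col - b * (k + 1) / 2.0) ** 2).sum())
    if A - C <= 0:
        return 0.0
    return num / (A - C)


def friedman_test(table: pd.DataFrame | np.ndarray,
                  exact_max_blocks: int = 8) -> dict:
    """Friedman test on a complete blocks (participants) x levels table.

    Rows with any missing value are excluded (complete cases).  Returns the
    tie-corrected chi-square statistic with its asymptotic p-value, and —
    when the number of complete blocks is at most ``exact_max_blocks`` —
    an exact p-value by full enumeration of within-block rank permutations.
    """
    arr = np.asarray(pd.DataFrame(table), dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    b, k = arr.shape
    if b < 2:
        raise ValueError("need at least 2 complete blocks")
    if k < 2:
        raise ValueError("need at least 2 levels")

    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    statistic = _friedman_statistic(ranks)
    p_chi2 = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0

    out = {"statistic": float(statistic), "p_value": p_chi2,
           "df": k - 1, "n_blocks": b, "exact_p": None,
           "exact_p_strict": None}
    if b <= exact_max_blocks and math.factorial(k) ** b <= 3_000_000:
        out["exact_p"], out["exact_p_strict"] = \
            _friedman_exact_p(ranks, statistic)
    return out


def _friedman_exact_p(ranks: np.ndarray,
                      observed: float) -> tuple[float, float]:
    """Exact permutation p (>= observed, and strictly >) by dynamic
    programming over block column-sum vectors.  The two values bracket the
    discreteness of the permutation distribution at the observed statistic;
    a continuous approximation is expected to land between them."""
    b, k = ranks.shape
    perms = list(itertools.permutations(range(k)))
    # distribution over column-sum vectors, built block by block
    dist: dict[tuple, int] = {tuple([0.0] * k): 1}
    for row in ranks:
        new: dict[tuple, int] = {}
        for vec, cnt in dist.items():
            for perm in perms:
                nv = tuple(vec[j] + row[perm[j]] for j in range(k))
                new[nv] = new.get(nv, 0) + cnt
        dist = new
    A = float((ranks ** 2).sum())
    C = b * k * (k + 1) ** 2 / 4.0
    denom = A - C
    total = sum(dist.values())
    if denom <= 0:
        return 1.0, 1.0
    ge = gt = 0
    center = b * (k + 1) / 2.0
    for vec, cnt in dist.items():
        q = (k - 1) * sum((v - center) ** 2 for v in vec) / denom
        if q >= observed - 1e-9:
            ge += cnt
            if q > observed + 1e-9:
                gt += cnt
    return ge / total, gt / total


def spearman(x, y) -> dict:
    """Tie-adjusted Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired complete observations")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": int(len(x))}
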